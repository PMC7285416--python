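import numpy as np
import pytest

from megax import ExpressionStudy, StudyEffect, StudyMetadata


@pytest.fixture
def toy_metadata():
    return StudyMetadata(study_id="TOY1", n_control=2, n_case=2, country="A", study_age_years=1.0)


@pytest.fixture
def toy_study(toy_metadata):
    """2 genes x 4 samples, already log2: gene G1 has LFC 3, G2 has LFC 0."""
    return ExpressionStudy(
        metadata=toy_metadata,
        genes=["G1", "G2"],
        values=np.array([[0.0, 2.0, 3.0, 5.0], [1.0, 3.0, 1.0, 3.0]]),
        group=["control", "control", "case", "case"],
        sample_ids=["s1", "s2", "s3", "s4"],
        scale="log2",
    )


def make_effects(lfcs, ses=None, gene="G"):
    ses = ses if ses is not None else [0.5] * len(lfcs)
    return [
        StudyEffect(study_id=f"S{i + 1}", gene=gene, lfc=float(l), se=float(s),
                    n_control=10, n_case=10)
        for i, (l, s) in enumerate(zip(lfcs, ses))
    ]


@pytest.fixture
def two_study_effects():
    """The hand-worked heterogeneity example: Q=8, ISq=87.5, tau2=1.75."""
    return make_effects([1.0, 3.0], [0.5, 0.5])
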