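import textwrap

import numpy as np
import pytest

from causallc import default_scenarios
from causallc.study_data import (
    BINARY,
    OutcomeSpec,
    StudyDesign,
    TreatmentBlock,
)

TOY_DESIGN_YAML = textwrap.dedent(
    """\
    id_column: id
    blocks:
      - index: 1
        treatments:
          - {name: treat, kind: binary}
    confounders_all: [risk]
    confounders_post: []
    external_covariates: []
    outcome_sets:
      primary:
        all: [out1, out2]
    continuous_columns: []
    """
)

TOY_COHORT_CSV = textwrap.dedent(
    """\
    id,risk,treat,out1,out2
    1,0,1,0,0
    2,1,1,1,0
    3,0,0,0,1
    4,1,0,1,1
    """
)


@pytest.fixture()
def toy_paths(tmp_path):
    design = tmp_path / "design.yaml"
    design.write_text(TOY_DESIGN_YAML)
    cohort = tmp_path / "cohort.csv"
    cohort.write_text(TOY_COHORT_CSV)
    return cohort, design


@pytest.fixture()
def toy_design():
    return StudyDesign(
        blocks=(TreatmentBlock(1, (("treat", BINARY),)),),
        confounders_all=("risk",),
        confounders_post=(),
        external_covariates=(),
        outcome_sets={"primary": OutcomeSpec(dimensions=(("all", ("out1", "out2")),))},
    )


@pytest.fixture(scope="session")
def scenarios():
    """Shared scenario library (intercept calibration runs once)."""
    return default_scenarios()


def brute_force_loglik(pi, cond_probs, Y, w):
    """Independent double-loop evaluator of the weighted mixture
    log-likelihood; deliberately naive."""
    total = 0.0
    for i in range(len(Y)):
        mix = 0.0
        for u in range(len(pi)):
            lik = pi[u]
            for r in range(Y.shape[1]):
                p = cond_probs[u][r]
                lik *= p if Y[i, r] == 1 else (1.0 - p)
            mix += lik
        total += w[i] * np.log(mix)
    return total
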