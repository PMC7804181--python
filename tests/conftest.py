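import numpy as np
import pytest

from mlcbias.simcohort import NONE, SAME, Cohort, default_positions, default_snp_ids


def make_cohort(
    genotypes,
    reported_y,
    true_y=None,
    liability_d=None,
    disease=None,
    sex=None,
    age=None,
    change_group=None,
    reason=None,
    drinker_status=None,
    causal_idx_y=None,
):
    """Hand-built cohort for unit tests; unspecified fields get neutral values."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    reported_y = np.asarray(reported_y, dtype=float)
    true_y = reported_y.copy() if true_y is None else np.asarray(true_y, float)
    return Cohort(
        genotypes=genotypes,
        positions=default_positions(m),
        snp_ids=default_snp_ids(m),
        true_y=true_y,
        reported_y=reported_y,
        liability_d=np.zeros(n) if liability_d is None else np.asarray(liability_d, float),
        disease=np.zeros(n, np.int8) if disease is None else np.asarray(disease, np.int8),
        sex=np.zeros(n, np.int8) if sex is None else np.asarray(sex, np.int8),
        age=np.full(n, 50.0) if age is None else np.asarray(age, float),
        change_group=np.full(n, SAME, object) if change_group is None else np.asarray(change_group, object),
        reason=np.full(n, NONE, object) if reason is None else np.asarray(reason, object),
        causal_idx_y=np.array([], int) if causal_idx_y is None else np.asarray(causal_idx_y, int),
        causal_idx_d=np.array([], int),
        true_beta_y=np.zeros(m),
        true_gamma_d=np.zeros(m),
        drinker_status=None if drinker_status is None else np.asarray(drinker_status, object),
    )


@pytest.fixture(scope="session")
def small_scenario_ii():
    """One moderate scenario-II cohort shared across tests (read-only)."""
    from mlcbias import ScenarioConfig, simulate_scenario

    return simulate_scenario(
        ScenarioConfig("II", n_individuals=4000, n_snps=300, n_causal_y=60, seed=11)
    )
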