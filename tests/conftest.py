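import io
import textwrap

import pytest

from gxe.cohort import read_cohort_table
from gxe.simulate import SimConfig, simulate_cohort

#: two complete 1:3 matched strata; one aspirin-exposed case per stratum
TOY_TABLE = textwrap.dedent(
    """\
    subject_id\tstratum_id\tis_case\tcenter\tperiod\tage\tsex\tindex_date\tdrug_events\tancestry_flag\treliability\trs2238631\trs689466
    S1\tM1\t1\tC1\tP1\t64\tM\t2014-03-10\taspirin:2014-03-08\twhite\t9\tT/C\tT/T
    S2\tM1\t0\tC1\tP1\t62\tM\t2014-03-11\t\twhite\t8\tT/T\tT/C
    S3\tM1\t0\tC1\tP1\t66\tM\t2014-03-12\taspirin:2014-01-02\twhite\t7\tT/T\tT/T
    S4\tM1\t0\tC1\tP1\t63\tM\t2014-03-13\t\twhite\t10\tC/C\tT/T
    S5\tM2\t1\tC2\tP1\t71\tF\t2014-05-01\taspirin:2014-04-30\twhite\t8\tT/T\tC/C
    S6\tM2\t0\tC2\tP1\t69\tF\t2014-05-02\t\twhite\t9\tT/C\tT/T
    S7\tM2\t0\tC2\tP1\t73\tF\t2014-05-03\t\twhite\t6\tT/T\tT/C
    S8\tM2\t0\tC2\tP1\t70\tF\t2014-05-04\taspirin:2014-05-01\twhite\t7\tT/T\tT/T
    """
)


@pytest.fixture
def toy_text():
    return TOY_TABLE


@pytest.fixture
def toy_cohort():
    return read_cohort_table(io.StringIO(TOY_TABLE))


@pytest.fixture(scope="session")
def null_cohort():
    """300 matched strata, no genotype or exposure effect (true RERI 0)."""
    cfg = SimConfig(n_strata=300, exposure_prev_controls=0.2, seed=101)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def effect_cohort():
    """1000 matched strata with or10=2, or01=1.5, true RERI 1 (or11=3.5)."""
    cfg = SimConfig(
        n_strata=1000, exposure_prev_controls=0.2,
        or10=2.0, or01=1.5, target_reri=1.0, seed=202,
    )
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth
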