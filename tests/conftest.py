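import hypothesis
import numpy as np
import pytest

from sdrscan import Sex, SexedSample

hypothesis.settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=25
)
hypothesis.settings.load_profile("suite")


def make_cohort(n_males: int = 7, n_females: int = 6) -> list[SexedSample]:
    return [SexedSample(f"M{i + 1:02d}", Sex.MALE) for i in range(n_males)] + [
        SexedSample(f"F{i + 1:02d}", Sex.FEMALE) for i in range(n_females)
    ]


@pytest.fixture(scope="session")
def cohort_13():
    return make_cohort()


@pytest.fixture(scope="session")
def xy_run(tmp_path_factory):
    """One simulated XY cohort and its full pipeline result, shared."""
    from sdrscan import make_fixture, run_pipeline, simulate_cohort

    base = tmp_path_factory.mktemp("xy_run")
    sim = simulate_cohort(make_fixture("xy_small", seed=11), base / "sim")
    result = run_pipeline(
        sim.sample_sheet, sim.depth_dir, sim.vcf, sim.contig_table,
        out_dir=base / "out",
    )
    return sim, result
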