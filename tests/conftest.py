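import pytest

from varprio.variant_io import Cohort, GenotypeCall, Sample, VariantRecord


CASE_IDS = ["case1", "case2", "case3", "case4"]
CONTROL_IDS = ["ctrl1", "ctrl2"]


@pytest.fixture(scope="session")
def panel_6():
    """A bare 4-case/2-control discovery panel."""
    samples = [Sample(id=s, phenotype="case") for s in CASE_IDS]
    samples += [Sample(id=s, phenotype="control") for s in CONTROL_IDS]
    return Cohort(samples=samples)


def make_variant(case_gts, control_gts, pos=1_000_000, **kwargs):
    """A VariantRecord with the given panel genotype pattern."""
    genotypes = dict(zip(CASE_IDS, case_gts)) | dict(zip(CONTROL_IDS, control_gts))
    defaults = dict(
        chrom="12",
        pos=pos,
        ref="C",
        alt="T",
        genotypes=genotypes,
        callers=frozenset({"caller_a"}),
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


@pytest.fixture(scope="session")
def discovery_pattern_variant():
    """The incompletely concordant pattern of a real discovery panel:
    two homozygous-risk cases, two homozygous-reference cases, one
    homozygous-reference control, one homozygous-risk control."""
    G = GenotypeCall
    return make_variant(
        [G.HOM_ALT, G.HOM_ALT, G.HOM_REF, G.HOM_REF],
        [G.HOM_REF, G.HOM_ALT],
    )


@pytest.fixture(scope="session")
def sim_bundle():
    """One default simulated study (cohort, truth, panel), seed 7."""
    from varprio.simulate import SimulationConfig, select_panel, simulate_cohort

    config = SimulationConfig(seed=7)
    cohort, truth = simulate_cohort(config)
    panel = select_panel(cohort, truth, scenario="informative")
    return config, cohort, truth, panel
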