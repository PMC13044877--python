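import pytest

from umrm.fragment_profiles import CEProfile, FragmentGroup
from umrm.records import POSITIVE, FeatureRecord
from umrm.synth_fixtures import GeneratorSpec, generate_run


def make_profile(
    observations: dict[float, float],
    fragment_mz: float = 150.0,
    precursor_mz: float = 400.0,
    rt_min: float = 5.0,
    polarity: str = POSITIVE,
) -> CEProfile:
    group = FragmentGroup(
        group_mz=fragment_mz,
        observations=dict(observations),
        _weight=sum(observations.values()),
    )
    return CEProfile(
        precursor_mz=precursor_mz,
        precursor_rt_min=rt_min,
        polarity=polarity,
        fragment=group,
    )


def make_feature(
    feature_id: str,
    mz: float,
    rt_min: float = 5.0,
    intensity: float = 1000.0,
    polarity: str = POSITIVE,
) -> FeatureRecord:
    return FeatureRecord(
        feature_id=feature_id,
        mz=mz,
        rt_min=rt_min,
        intensity=intensity,
        polarity=polarity,
    )


@pytest.fixture(scope="session")
def noiseless_run():
    """A 100-compound, 60-ISF noiseless synthetic run shared across tests."""
    spec = GeneratorSpec.noiseless(n_compounds=100, isf_fraction=0.6)
    return generate_run(spec, seed=7)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_run):
    from umrm.pipeline import run_pipeline

    return run_pipeline(noiseless_run.features, noiseless_run.spectra)
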