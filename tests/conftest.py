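import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metscan.mbp_library import MetalBindingPattern, dedupe
from metscan.mbp_matcher import MatchPolicy
from metscan.synthetic_data import PlantSpec, SyntheticProteomeSpec, make_proteome

settings.register_profile(
    "default",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def default_policy():
    return MatchPolicy()


@pytest.fixture
def zinc_finger_mbp():
    # C-x3-C-x13-H-x4-H, a classic treble-clef-like spacing
    return MetalBindingPattern(
        mbp_id="Zn_CCHH_4-14-5", element="Zn", ligands=tuple("CCHH"), gaps=(4, 14, 5)
    )


@pytest.fixture
def cadmium_mbp():
    return MetalBindingPattern(
        mbp_id="Cd_CCCC_2-6-2", element="Cd", ligands=tuple("CCCC"), gaps=(2, 6, 2)
    )


@pytest.fixture
def ef_hand_mbp():
    # EF-hand-like calcium loop: acidic ligands at short spacing
    return MetalBindingPattern(
        mbp_id="Ca_DDDE_2-2-3", element="Ca", ligands=tuple("DDDE"), gaps=(2, 2, 3)
    )


@pytest.fixture
def small_library(zinc_finger_mbp, cadmium_mbp, ef_hand_mbp):
    return dedupe([zinc_finger_mbp, cadmium_mbp, ef_hand_mbp])


@pytest.fixture(scope="session")
def planted_bundle():
    """A 300-protein proteome with intact, perturbed-within-tolerance and
    perturbed-beyond-tolerance plants plus calcium co-plants."""
    zn = MetalBindingPattern(
        mbp_id="Zn_CCHH_4-14-5", element="Zn", ligands=tuple("CCHH"), gaps=(4, 14, 5)
    )
    cd = MetalBindingPattern(
        mbp_id="Cd_CCCC_2-6-2", element="Cd", ligands=tuple("CCCC"), gaps=(2, 6, 2)
    )
    ca = MetalBindingPattern(
        mbp_id="Ca_DDDE_2-2-3", element="Ca", ligands=tuple("DDDE"), gaps=(2, 2, 3)
    )
    spec = SyntheticProteomeSpec(
        n_proteins=300,
        plants=(
            PlantSpec(mbp=zn, copies=25),
            PlantSpec(mbp=cd, copies=20, per_gap_perturbation=(0, 1, 0)),  # within ±1
            PlantSpec(mbp=cd, copies=10, per_gap_perturbation=(0, 4, 0)),  # beyond
        ),
        co_plant=(ca, 0.3),
        annotation_plan={
            "ec_class": {"1": 0.1, "2": 0.15, "3": 0.15, "none": 0.6},
            "localization": {
                "membrane": 0.4,
                "cytoplasm": 0.2,
                "ribosome": 0.1,
                "other": 0.1,
                "none": 0.2,
            },
        },
        seed=42,
    )
    return make_proteome(spec)
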