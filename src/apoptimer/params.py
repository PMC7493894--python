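"""Kinetic parameters, initial states and model variants.

Units are micromolar (uM) and minutes throughout; every rate constant is
converted to uM/min at load time.  Second-order rates are uM^-1 min^-1,
first-order rates min^-1.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "KineticParameterSet",
    "InitialState",
    "ModelVariant",
    "VARIANTS",
    "default_parameters",
    "default_initial_state",
    "default_ranges",
]


@dataclass(frozen=True)
class KineticParameterSet:
    """All rate constants of the apoptosis-execution reaction network.

    The cooperative recruitment step is parameterised by a weak *primary*
    binding of a single pro-caspase 9 (PC9) onto the empty apoptosome CARD
    platform followed by a stronger *secondary* binding of a second PC9
    directly into a homodimer.  Cleaved caspase 9 (C9-35/12) re-binds the
    platform only weakly; that weak affinity is the molecular timer.

    Parameters
    ----------
    k_assembly : uM^-1 min^-1
        Effective bimolecular rate of APAF1 activation by cytosolic
        cytochrome c; seven activated APAF1 (with seven CytC) lump into one
        platform.
    katp_uM : uM
        Half-saturation of the ATP dependence of assembly; ATP is
        non-limiting at cellular concentrations (~1 mM).
    kon_primary, koff_primary
        First PC9 on/off an empty platform.
    kon_secondary, koff_secondary
        Second PC9 on/off a singly occupied platform (cooperative step).
    k_auto : min^-1
        Autocatalytic cleavage of the platform-bound PC9 homodimer; both
        protomers convert to C9-35/12, one remaining bound, one released.
    kon_c9, koff_c9
        C9-35/12 on/off the empty platform (weak; timer).
    k_pc9, k_c9 : uM^-1 min^-1
        Catalytic rates for cleavage of the IETD site of pro-caspase 3
        (PC3) by active PC9-apoptosome moieties and by the active
        C9-apoptosome respectively.
    k_devd : uM^-1 min^-1
        Cleavage of the DEVD-site effector substrate by active caspase 3.
    kon_xiap_c3, koff_xiap_c3
        XIAP (BIR2 site) binding of caspase 3.
    kon_xiap_c9, koff_xiap_c9
        XIAP (BIR3 site) binding of C9-35/12, free or platform-bound.
    kon_smac_xiap, koff_smac_xiap
        SMAC neutralisation of XIAP.
    """

    k_assembly: float
    kon_primary: float
    koff_primary: float
    kon_secondary: float
    koff_secondary: float
    k_auto: float
    kon_c9: float
    koff_c9: float
    k_pc9: float
    k_c9: float
    k_devd: float
    kon_xiap_c3: float
    koff_xiap_c3: float
    kon_xiap_c9: float
    koff_xiap_c9: float
    kon_smac_xiap: float
    koff_smac_xiap: float
    katp_uM: float = 100.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"rate constant {name} must be >= 0, got {value}")

    def validate_cooperativity(self) -> None:
        """Enforce the cooperative ordering and the timer precondition."""
        if not self.kon_primary < self.kon_secondary:
            raise ValueError("cooperativity requires kon_primary < kon_secondary")
        if not self.koff_primary > self.koff_secondary:
            raise ValueError("cooperativity requires koff_primary > koff_secondary")
        kd_c9 = self.koff_c9 / self.kon_c9
        kd_secondary = self.koff_secondary / self.kon_secondary
        if not kd_c9 > kd_secondary:
            raise ValueError(
                "molecular timer requires C9 affinity weaker than secondary PC9 "
                f"(KD_C9={kd_c9:.3g} uM <= KD_secondary={kd_secondary:.3g} uM)"
            )

    def replace(self, **changes) -> "KineticParameterSet":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class InitialState:
    """Per-species initial concentrations in uM.

    Cytochrome c and SMAC start in the mitochondrial pools; MOMP (see
    :func:`apoptimer.core.apply_momp`) transfers a fraction to the cytosol.
    All complexes start at zero.
    """

    cytc_mito: float = 10.0
    smac_mito: float = 1.0
    cytc: float = 0.0
    smac: float = 0.0
    apaf1: float = 0.4
    pc9: float = 0.04
    pc3: float = 0.2
    xiap: float = 0.3
    substrate: float = 1.0
    atp: float = 920.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"initial concentration {name} must be >= 0")

    def replace(self, **changes) -> "InitialState":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ModelVariant:
    """Switchable regulatory layers of the execution network.

    ``timer_enabled=False`` assigns cleaved C9 the same (strong) apoptosome
    binding kinetics as secondarily bound PC9, so apoptosome activity
    persists; XIAP inhibition of C9-35/12 is retained, keeping the two
    regulatory layers independently switchable.  ``pc9_cleavable=False``
    models the non-cleavable PC9 mutant: no C9 species ever forms, hence
    neither the timer nor XIAP inhibition of C9 can act.
    """

    timer_enabled: bool = True
    xiap_present: bool = True
    pc9_cleavable: bool = True
    synthesis_degradation_enabled: bool = False
    name: str = "custom"


VARIANTS: dict[str, ModelVariant] = {
    "normal": ModelVariant(name="normal"),
    "no_xiap": ModelVariant(xiap_present=False, name="no_xiap"),
    "no_timer": ModelVariant(timer_enabled=False, name="no_timer"),
    "no_xiap_no_timer": ModelVariant(
        timer_enabled=False, xiap_present=False, name="no_xiap_no_timer"
    ),
    "noncleavable": ModelVariant(pc9_cleavable=False, name="noncleavable"),
}


def _load_yaml(name: str) -> dict:
    with resources.files("apoptimer.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def default_parameters() -> KineticParameterSet:
    """Calibrated default rate constants (see ``data/defaults.yaml``)."""
    return KineticParameterSet(**_load_yaml("defaults.yaml")["parameters"])


def default_initial_state(**overrides) -> InitialState:
    """HeLa-like baseline initial state."""
    cfg = _load_yaml("defaults.yaml")["initial_state"]
    cfg.update(overrides)
    return InitialState(**cfg)


def default_ranges() -> dict[str, tuple[float, float]]:
    """Physiological concentration ranges used by the screens (uM)."""
    raw = _load_yaml("defaults.yaml")["ranges"]
    return {k: (float(v[0]), float(v[1])) for k, v in raw.items()}


def load_config(path: str | Path) -> tuple[KineticParameterSet, InitialState, ModelVariant, dict]:
    """Read a structured config file (YAML) with blocks
    parameters / initial_state / variant / solver."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    params = KineticParameterSet(**cfg.get("parameters", {})) if "parameters" in cfg else default_parameters()
    state = InitialState(**cfg.get("initial_state", {})) if "initial_state" in cfg else default_initial_state()
    vdict = cfg.get("variant", {})
    if isinstance(vdict, str):
        variant = VARIANTS[vdict]
    else:
        variant = ModelVariant(**vdict) if vdict else VARIANTS["normal"]
    solver = cfg.get("solver", {})
    return params, state, variant, solver
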