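"""Model parameters: shared constants, per-motif schemas, grid bounds and
reference optima.

The circuit family shares a fixed backbone (2000 Kenyon cells driven at 3 Hz
by an odor, uniform initial KC>MBON weights of 0.083, three first-order and
three second-order conditioning trials) and differs only in how the
dopaminergic neuron (DAN) receives network-internal input. Each motif has
four free parameters that were screened on a regular 100-point-per-axis grid;
the most central optimal learner of each screen is stored here as the
motif's reference parameter combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

# Backbone constants shared by every motif.
N_KC = 2000
KC_BASELINE = 0.0  # Hz, spontaneous Kenyon-cell rate
ODOR_ACTIVATION = 3.0  # Hz, rate of odor-activated Kenyon cells
ACTIVATION_FRACTION = 0.10  # fraction of KCs active per odor
INIT_KC_MBON = 0.083  # initial KC>MBON weight, both valences
TRIALS_FOC = 3
TRIALS_SOC = 3
MASTER_SEED = 999

# Biological-plausibility screening caps (not saturations in the dynamics).
DAN_RATE_CAP = 20.0  # Hz
MBON_RATE_CAP = 50.0  # Hz

MODEL_IDS = ("basic", "m1", "m2", "m3", "m4", "m5")


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent run configurations."""


@dataclass
class CircuitParams:
    """All constants of one circuit instance.

    Only the fields relevant for ``model_id`` are consulted by the update
    engine; the rest stay at their inert defaults (zero weight / zero rate),
    which makes every extended motif collapse onto the basic circuit when its
    extension parameters are zeroed.
    """

    model_id: str
    n_kc: int = N_KC
    init_kc_mbon_plus: float = INIT_KC_MBON
    init_kc_mbon_minus: float = INIT_KC_MBON
    alpha_kc_mbon_minus: float = 0.0  # depression rate at KC>MBON− synapses
    dan_activation: float = 0.0  # Hz, external DAN input on rewarded trials
    # model 1 / model 2: feed-forward KC>DAN synapses
    init_kc_dan: float = 0.0
    # model 1: plastic excitatory KC>KC recurrence
    init_kc_kc: float = 0.0
    alpha_kc_kc: float = 0.0
    # model 2: plastic KC>DAN synapses
    alpha_kc_dan: float = 0.0
    # model 3 / model 5: excitatory MBON+>DAN feedback
    init_mbon_plus_dan: float = 0.0
    # model 3 / model 4: inhibitory MBON−>DAN feedback
    init_mbon_minus_dan: float = 0.0
    # model 5: potentiation rate of the MBON+>DAN synapse
    alpha_mbon_plus_dan: float = 0.0
    # model 4: tonic DAN drive
    r_dan_baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ConfigurationError(f"unknown model_id {self.model_id!r}")
        if self.n_kc < 1:
            raise ConfigurationError("n_kc must be >= 1")
        for f in fields(self):
            if f.name in ("model_id", "n_kc"):
                continue
            if getattr(self, f.name) < 0:
                raise ConfigurationError(f"{f.name} must be non-negative")

    def with_updates(self, **kwargs: float) -> "CircuitParams":
        return replace(self, **kwargs)


# Free (grid-searched) parameters per motif, in screen order, with bounds.
# Model 1 additionally carries a degenerate init_kc_kc = 0 axis in the
# published screen (min = max = 0); it is treated as fixed here.
GRID_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "m1": {
        "init_kc_dan": (0.0, 0.001),
        "alpha_kc_mbon_minus": (0.001, 0.004),
        "alpha_kc_kc": (0.0, 0.004),
        "dan_activation": (1.0, 10.0),
    },
    "m2": {
        "init_kc_dan": (0.0, 0.001),
        "alpha_kc_mbon_minus": (0.001, 0.004),
        "alpha_kc_dan": (0.0, 0.001),
        "dan_activation": (1.0, 10.0),
    },
    "m3": {
        "init_mbon_plus_dan": (0.0, 1.0),
        "init_mbon_minus_dan": (0.0, 1.0),
        "alpha_kc_mbon_minus": (0.001, 0.004),
        "dan_activation": (1.0, 10.0),
    },
    "m4": {
        "init_mbon_minus_dan": (0.0, 0.5),
        "alpha_kc_mbon_minus": (0.001, 0.004),
        "r_dan_baseline": (0.0, 30.0),
        "dan_activation": (1.0, 10.0),
    },
    "m5": {
        "init_mbon_plus_dan": (0.0, 0.4),
        "alpha_kc_mbon_minus": (0.001, 0.004),
        "alpha_mbon_plus_dan": (0.001, 0.01),
        "dan_activation": (1.0, 10.0),
    },
}

# Most central optimal learner of each 100^4 screen, stored as indices into
# the 100-point grid so the values are exact grid points (they round to the
# published six-decimal figures, e.g. 7.272727 or 0.003182).
_OPTIMUM_GRID_INDEX: dict[str, dict[str, int]] = {
    "m1": {
        "init_kc_dan": 99,  # 0.001
        "alpha_kc_mbon_minus": 99,  # 0.004
        "alpha_kc_kc": 4,  # 0.000162
        "dan_activation": 69,  # 7.272727
    },
    "m2": {
        "init_kc_dan": 50,  # 0.000505
        "alpha_kc_mbon_minus": 77,  # 0.003333
        "alpha_kc_dan": 67,  # 0.000677
        "dan_activation": 52,  # 5.727273
    },
    "m3": {
        "init_mbon_plus_dan": 27,  # 0.272727
        "init_mbon_minus_dan": 26,  # 0.262626
        "alpha_kc_mbon_minus": 70,  # 0.003121
        "dan_activation": 44,  # 5.0
    },
    "m4": {
        "init_mbon_minus_dan": 26,  # 0.131313
        "alpha_kc_mbon_minus": 72,  # 0.003182
        "r_dan_baseline": 37,  # 11.212121
        "dan_activation": 30,  # 3.727273
    },
    "m5": {
        "init_mbon_plus_dan": 20,  # 0.080808
        "alpha_kc_mbon_minus": 72,  # 0.003182
        "alpha_mbon_plus_dan": 22,  # 0.003
        "dan_activation": 41,  # 4.727273
    },
}

GRID_POINTS_DEFAULT = 100


def free_parameters(model_id: str) -> list[str]:
    """Names of the four grid-searched parameters of ``model_id``."""
    if model_id not in GRID_BOUNDS:
        raise ConfigurationError(f"no parameter grid for model {model_id!r}")
    return list(GRID_BOUNDS[model_id])


def parameter_ranges(model_id: str) -> np.ndarray:
    """max − min per free parameter (used to scale the hypersphere sweep)."""
    return np.array([hi - lo for lo, hi in GRID_BOUNDS[model_id].values()])


def reference_optimum(model_id: str) -> dict[str, float]:
    """The motif's most central optimal learner as {parameter: value}."""
    if model_id not in _OPTIMUM_GRID_INDEX:
        raise ConfigurationError(f"no reference optimum for model {model_id!r}")
    out: dict[str, float] = {}
    for name, idx in _OPTIMUM_GRID_INDEX[model_id].items():
        lo, hi = GRID_BOUNDS[model_id][name]
        out[name] = float(np.linspace(lo, hi, GRID_POINTS_DEFAULT)[idx])
    return out


def make_params(model_id: str, combo: dict[str, float] | None = None,
                **overrides: float) -> CircuitParams:
    """Build :class:`CircuitParams` for a motif from a free-parameter combo.

    With ``combo=None`` the motif's reference optimum is used. Model 1's
    fixed KC>KC initialisation (0) is applied automatically.
    """
    if combo is None and model_id != "basic":
        combo = reference_optimum(model_id)
    values = dict(combo or {})
    values.update(overrides)
    return CircuitParams(model_id=model_id, **values)
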