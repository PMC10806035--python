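"""Single-step rate/weight update engine for the basic circuit and the five
second-order-conditioning motifs.

The circuit is trial-based and rate-based. Per step, in order:

1. Kenyon-cell rates. All motifs except model 1 use the stimulus drive
   directly. Model 1 adds one pass of the odor-driven rates through the
   learned excitatory KC>KC recurrence, ``r = drive + Wᵀ·drive`` (rectified);
   the recurrence is deliberately not iterated to a fixed point.
2. MBON rates: inner products of the KC rates with the KC>MBON⁺/⁻ weight
   vectors.
3. DAN rate: external reward input plus the motif-specific network-internal
   pathway, rectified at zero (the MBON−>DAN feedback of models 3/4 is
   inhibitory and could otherwise drive the sum negative).
4. If plasticity is enabled, all of the motif's rules fire synchronously from
   this step's rates and the pre-update weights:

   - two-factor depression of active KC>MBON⁻ synapses, gated by the DAN:
     ``w ← max(0, w − α·R_DAN)`` (weights cannot go negative);
   - model 1: Hebbian potentiation of KC>KC weights for co-active pairs;
   - model 2: DAN-gated potentiation of active KC>DAN synapses;
   - model 5: coincidence potentiation of the MBON⁺>DAN synapse.

No rule ever touches the KC>MBON⁺ weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import KC_BASELINE, CircuitParams

__all__ = [
    "CircuitState", "RateReadout", "initial_state", "kc_rates", "mbon_rates",
    "dan_rate", "step", "depress_kc_mbon_minus", "potentiate_kc_kc",
    "potentiate_kc_dan", "potentiate_mbon_dan",
]


@dataclass
class CircuitState:
    """All synaptic weights of one circuit instance (mutated by learning)."""

    w_kc_mbon_plus: np.ndarray
    w_kc_mbon_minus: np.ndarray
    w_kc_dan: np.ndarray | None = None     # models 1 (fixed) and 2 (plastic)
    w_kc_kc: np.ndarray | None = None      # model 1
    w_mbon_plus_dan: float = 0.0           # models 3 and 5
    w_mbon_minus_dan: float = 0.0          # models 3 and 4

    def copy(self) -> "CircuitState":
        return CircuitState(
            w_kc_mbon_plus=self.w_kc_mbon_plus.copy(),
            w_kc_mbon_minus=self.w_kc_mbon_minus.copy(),
            w_kc_dan=None if self.w_kc_dan is None else self.w_kc_dan.copy(),
            w_kc_kc=None if self.w_kc_kc is None else self.w_kc_kc.copy(),
            w_mbon_plus_dan=self.w_mbon_plus_dan,
            w_mbon_minus_dan=self.w_mbon_minus_dan,
        )

    def save_npz(self, path) -> None:
        payload = {"w_kc_mbon_plus": self.w_kc_mbon_plus,
                   "w_kc_mbon_minus": self.w_kc_mbon_minus,
                   "w_mbon_plus_dan": np.array(self.w_mbon_plus_dan),
                   "w_mbon_minus_dan": np.array(self.w_mbon_minus_dan)}
        if self.w_kc_dan is not None:
            payload["w_kc_dan"] = self.w_kc_dan
        if self.w_kc_kc is not None:
            payload["w_kc_kc"] = self.w_kc_kc
        np.savez_compressed(path, **payload)


@dataclass(frozen=True)
class RateReadout:
    """Per-step firing rates (Hz) and the DAN input decomposition."""

    r_kc: np.ndarray
    r_mbon_plus: float
    r_mbon_minus: float
    r_dan: float
    ip_ext: float
    ip_int: float


def initial_state(params: CircuitParams,
                  w_plus: np.ndarray | None = None,
                  w_minus: np.ndarray | None = None) -> CircuitState:
    """Naive pre-training state.

    ``w_plus``/``w_minus`` override the uniform initial KC>MBON weight
    vectors; the robustness experiments use this for connectivity masks and
    weight jitter.
    """
    n = params.n_kc
    wp = np.full(n, params.init_kc_mbon_plus) if w_plus is None else np.asarray(w_plus, float).copy()
    wm = np.full(n, params.init_kc_mbon_minus) if w_minus is None else np.asarray(w_minus, float).copy()
    if wp.shape != (n,) or wm.shape != (n,):
        raise ValueError("KC>MBON weight vectors must have length n_kc")
    state = CircuitState(w_kc_mbon_plus=wp, w_kc_mbon_minus=wm)
    if params.model_id in ("m1", "m2"):
        state.w_kc_dan = np.full(n, params.init_kc_dan)
    if params.model_id == "m1":
        state.w_kc_kc = np.full((n, n), params.init_kc_kc)
    if params.model_id in ("m3", "m5"):
        state.w_mbon_plus_dan = params.init_mbon_plus_dan
    if params.model_id in ("m3", "m4"):
        state.w_mbon_minus_dan = params.init_mbon_minus_dan
    return state


def kc_rates(params: CircuitParams, state: CircuitState,
             stimulus_drive: np.ndarray) -> np.ndarray:
    """Kenyon-cell rates for one stimulus presentation."""
    drive = np.asarray(stimulus_drive, float)
    if drive.shape != (params.n_kc,):
        raise ValueError("stimulus drive must have length n_kc")
    if params.model_id == "m1":
        # one-pass propagation of the odor-driven rates through the
        # learned recurrence; see module docstring
        return np.maximum(0.0, drive + state.w_kc_kc.T @ drive)
    return np.maximum(0.0, drive)


def mbon_rates(kc: np.ndarray, state: CircuitState) -> tuple[float, float]:
    """(R_MBON⁺, R_MBON⁻): inner products of KC rates with the weight vectors."""
    kc = np.asarray(kc, float)
    if kc.shape != state.w_kc_mbon_plus.shape:
        raise ValueError("KC rate vector does not match weight dimension")
    return float(kc @ state.w_kc_mbon_plus), float(kc @ state.w_kc_mbon_minus)


def dan_rate(params: CircuitParams, state: CircuitState, ip_ext: float,
             kc: np.ndarray, r_mbon_plus: float, r_mbon_minus: float) -> tuple[float, float]:
    """(R_DAN, Ip_int). External reward input plus the motif's internal pathway."""
    m = params.model_id
    if m == "basic":
        ip_int = 0.0
    elif m in ("m1", "m2"):
        ip_int = float(kc @ state.w_kc_dan)
    elif m == "m3":
        ip_int = r_mbon_plus * state.w_mbon_plus_dan - r_mbon_minus * state.w_mbon_minus_dan
    elif m == "m4":
        ip_int = params.r_dan_baseline - r_mbon_minus * state.w_mbon_minus_dan
    elif m == "m5":
        ip_int = r_mbon_plus * state.w_mbon_plus_dan
    else:  # pragma: no cover - guarded in CircuitParams
        raise ValueError(f"unknown model_id {m!r}")
    return max(0.0, ip_ext + ip_int), ip_int


def depress_kc_mbon_minus(state: CircuitState, kc: np.ndarray, r_dan: float,
                          alpha: float) -> None:
    """Dopamine-gated two-factor depression of active KC>MBON⁻ synapses."""
    if r_dan < 0:
        raise ValueError("DAN rate must be non-negative")
    active = kc > 0
    w = state.w_kc_mbon_minus
    w[active] = np.maximum(0.0, w[active] - alpha * r_dan)


def potentiate_kc_kc(state: CircuitState, kc: np.ndarray, alpha_kc_kc: float) -> None:
    """Model 1: increment w_ij for every pair of co-active KCs."""
    active = np.flatnonzero(kc > KC_BASELINE)
    if active.size:
        state.w_kc_kc[np.ix_(active, active)] += alpha_kc_kc


def potentiate_kc_dan(state: CircuitState, kc: np.ndarray, r_dan: float,
                      alpha_kc_dan: float) -> None:
    """Model 2: DAN-gated potentiation of active KC>DAN synapses."""
    active = kc > 0
    state.w_kc_dan[active] += alpha_kc_dan * r_dan


def potentiate_mbon_dan(state: CircuitState, r_mbon_plus: float, r_dan: float,
                        alpha: float) -> None:
    """Model 5: strengthen MBON⁺>DAN when MBON⁺ and DAN are co-active."""
    if r_mbon_plus > 0:
        state.w_mbon_plus_dan += alpha * r_dan


def step(params: CircuitParams, state: CircuitState, stimulus_drive: np.ndarray,
         reward_on: bool, plasticity_on: bool) -> RateReadout:
    """One simulation step: rates, then (optionally) all plasticity rules.

    Plasticity is synchronous — every rule reads this step's rates and the
    pre-update weights. Mutates ``state`` iff ``plasticity_on``.
    """
    kc = kc_rates(params, state, stimulus_drive)
    r_plus, r_minus = mbon_rates(kc, state)
    ip_ext = params.dan_activation if reward_on else 0.0
    r_dan, ip_int = dan_rate(params, state, ip_ext, kc, r_plus, r_minus)
    if plasticity_on:
        depress_kc_mbon_minus(state, kc, r_dan, params.alpha_kc_mbon_minus)
        if params.model_id == "m1":
            potentiate_kc_kc(state, kc, params.alpha_kc_kc)
        elif params.model_id == "m2":
            potentiate_kc_dan(state, kc, r_dan, params.alpha_kc_dan)
        elif params.model_id == "m5":
            potentiate_mbon_dan(state, r_plus, r_dan, params.alpha_mbon_plus_dan)
    return RateReadout(r_kc=kc, r_mbon_plus=r_plus, r_mbon_minus=r_minus,
                       r_dan=r_dan, ip_ext=ip_ext, ip_int=ip_int)
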