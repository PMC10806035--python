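"""Conditioning protocol: rewarded first-order trials with odor 1, unrewarded
second-order trials with the odor-1+odor-2 compound, valence tests, the
unrewarded odor-3 extension, and overlap sweeps.

Learning is quantified by the approach bias
``B = (R_MBON⁺ − R_MBON⁻) / (R_MBON⁺ + R_MBON⁻)`` of each odor presented
alone with plasticity disabled. Tests present each odor for exactly one step
(rates are static given the weights, so duration is irrelevant); test-step
rates count toward the logged maxima used by the rate-cap screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import circuit
from .odors import (OdorLibrary, generate_odor_library, kc_drive,
                    make_compound)
from .params import TRIALS_FOC, TRIALS_SOC, CircuitParams, ConfigurationError
from .seeding import spawn_rng

TEST_ODORS = (1, 2, 3)


@dataclass(frozen=True)
class ProtocolSpec:
    """Schedule of the conditioning experiment (defaults: 3 FOC + 3 SOC
    single-step trials, fixed 50%-subsampled compound)."""

    trials_foc: int = TRIALS_FOC
    trials_soc: int = TRIALS_SOC
    steps_per_trial: int = 1
    compound_mode: str = "subsampled"
    extension_odor3_trials: int = 0
    redraw_compound_each_trial: bool = False

    def __post_init__(self) -> None:
        if min(self.trials_foc, self.trials_soc, self.extension_odor3_trials) < 0:
            raise ConfigurationError("trial counts must be >= 0")
        if self.steps_per_trial < 1:
            raise ConfigurationError("steps_per_trial must be >= 1")


@dataclass(frozen=True)
class BiasReport:
    """Approach bias and MBON rates of one odor at one test point."""

    phase: str
    odor: int
    bias: float
    r_mbon_plus: float
    r_mbon_minus: float
    max_dan_seen: float
    max_mbon_seen: float


@dataclass
class ProtocolResult:
    state: circuit.CircuitState
    reports: list
    rate_log: pd.DataFrame
    max_dan: float
    max_mbon: float

    def bias(self, phase: str, odor: int) -> float:
        for rep in self.reports:
            if rep.phase == phase and rep.odor == odor:
                return rep.bias
        raise KeyError((phase, odor))

    def reports_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.reports])


def approach_bias(r_plus: float, r_minus: float) -> float:
    """Valence readout in [−1, 1]; defined as 0 when both rates are 0."""
    if r_plus < 0 or r_minus < 0:
        raise ValueError("MBON rates must be non-negative")
    total = r_plus + r_minus
    if total == 0:
        return 0.0
    return (r_plus - r_minus) / total


class _Tracker:
    """Running maxima of DAN and MBON rates plus the per-step rate log."""

    def __init__(self) -> None:
        self.max_dan = 0.0
        self.max_mbon = 0.0
        self.rows: list[dict] = []
        self._step = 0

    def record(self, phase: str, trial: int, stimulus: str,
               out: circuit.RateReadout) -> None:
        self.max_dan = max(self.max_dan, out.r_dan)
        self.max_mbon = max(self.max_mbon, out.r_mbon_plus, out.r_mbon_minus)
        self.rows.append({
            "step": self._step, "trial": trial, "phase": phase,
            "stimulus": stimulus, "r_mbon_plus": out.r_mbon_plus,
            "r_mbon_minus": out.r_mbon_minus, "r_dan": out.r_dan,
        })
        self._step += 1

    def log(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["step", "trial", "phase", "stimulus",
                                                "r_mbon_plus", "r_mbon_minus", "r_dan"])


def run_test(params: CircuitParams, state: circuit.CircuitState,
             library: OdorLibrary, phase: str = "test",
             odors=TEST_ODORS, tracker: _Tracker | None = None) -> list:
    """Present each odor alone, reward off and plasticity off; the state is
    left untouched."""
    tracker = tracker or _Tracker()
    reports = []
    for odor in odors:
        drive = kc_drive(library.pattern(odor), params.n_kc)
        out = circuit.step(params, state, drive, reward_on=False, plasticity_on=False)
        tracker.record(phase, -1, f"odor{odor}", out)
        reports.append(BiasReport(
            phase=phase, odor=odor,
            bias=approach_bias(out.r_mbon_plus, out.r_mbon_minus),
            r_mbon_plus=out.r_mbon_plus, r_mbon_minus=out.r_mbon_minus,
            max_dan_seen=tracker.max_dan, max_mbon_seen=tracker.max_mbon))
    return reports


def _train(params, state, drive_label, drive, trials, steps, reward_on, phase,
           tracker) -> None:
    for trial in range(trials):
        for _ in range(steps):
            out = circuit.step(params, state, drive, reward_on=reward_on,
                               plasticity_on=True)
            tracker.record(phase, trial, drive_label, out)


def run_foc_soc_protocol(params: CircuitParams, library: OdorLibrary,
                         spec: ProtocolSpec = ProtocolSpec(),
                         seed: int | None = None,
                         state: circuit.CircuitState | None = None) -> ProtocolResult:
    """The full conditioning schedule.

    Rewarded FOC trials with odor 1 → test of odors 1–3 → unrewarded SOC
    trials with the odor-1+odor-2 compound → test of odors 1–3, optionally
    followed by unrewarded odor-3 extension trials and a third test. The
    compound subsample is drawn once per experiment by default (config flag
    to redraw each trial). ``state`` lets robustness experiments inject
    perturbed initial weights.
    """
    seed = library.seed if seed is None else seed
    tracker = _Tracker()
    state = circuit.initial_state(params) if state is None else state
    reports: list[BiasReport] = []

    foc_drive = kc_drive(library.pattern(1), params.n_kc)
    _train(params, state, "odor1", foc_drive, spec.trials_foc,
           spec.steps_per_trial, True, "FOC", tracker)
    reports += run_test(params, state, library, "post_FOC", tracker=tracker)

    rng = spawn_rng(seed, "compound")
    compound = make_compound(library.pattern(1), library.pattern(2),
                             mode=spec.compound_mode, seed=rng)
    for trial in range(spec.trials_soc):
        if spec.redraw_compound_each_trial and trial > 0:
            compound = make_compound(library.pattern(1), library.pattern(2),
                                     mode=spec.compound_mode, seed=rng)
        for _ in range(spec.steps_per_trial):
            out = circuit.step(params, state, kc_drive(compound, params.n_kc),
                               reward_on=False, plasticity_on=True)
            tracker.record("SOC", trial, "odor1_2", out)
    reports += run_test(params, state, library, "post_SOC", tracker=tracker)

    if spec.extension_odor3_trials:
        ext_drive = kc_drive(library.pattern(3), params.n_kc)
        _train(params, state, "odor3", ext_drive, spec.extension_odor3_trials,
               spec.steps_per_trial, False, "EXT", tracker)
        reports += run_test(params, state, library, "post_EXT", tracker=tracker)

    return ProtocolResult(state=state, reports=reports, rate_log=tracker.log(),
                          max_dan=tracker.max_dan, max_mbon=tracker.max_mbon)


def run_odor3_extension(params: CircuitParams, state: circuit.CircuitState,
                        library: OdorLibrary, trials: int = 3,
                        steps_per_trial: int = 1) -> BiasReport:
    """Unrewarded odor-3 trials (plasticity on) after SOC, then a test.

    Measures unwanted generalization of the reward association onto the
    novel odor: motifs whose DAN responds unspecifically to any odor acquire
    an odor-3 bias here. Mutates ``state``.
    """
    tracker = _Tracker()
    drive = kc_drive(library.pattern(3), params.n_kc)
    _train(params, state, "odor3", drive, trials, steps_per_trial, False,
           "EXT", tracker)
    return run_test(params, state, library, "post_EXT", odors=(3,),
                    tracker=tracker)[0]


def overlap_sweep(params: CircuitParams, overlaps=(0.0, 0.25, 0.5, 0.75, 1.0),
                  target_pair: tuple[int, int] = (3, 1),
                  seed: int | None = None,
                  spec: ProtocolSpec = ProtocolSpec()) -> pd.DataFrame:
    """Re-run the full protocol at each overlap level of one odor pair.

    Returns one row per (overlap, test phase, odor) with the bias and MBON
    rates. ``target_pair`` is (1, 2), (3, 1) or (3, 2).
    """
    rows = []
    for overlap in overlaps:
        library = generate_odor_library(
            n_kc=params.n_kc, overlap_spec={tuple(target_pair): float(overlap)},
            seed=seed if seed is not None else 999)
        result = run_foc_soc_protocol(params, library, spec)
        for rep in result.reports:
            rows.append({"model": params.model_id, "overlap": overlap,
                         "pair": f"{target_pair[0]}-{target_pair[1]}",
                         "phase": rep.phase, "odor": rep.odor, "bias": rep.bias,
                         "r_mbon_plus": rep.r_mbon_plus,
                         "r_mbon_minus": rep.r_mbon_minus,
                         "max_dan": result.max_dan, "max_mbon": result.max_mbon,
                         "compound_mode": spec.compound_mode})
    return pd.DataFrame(rows)
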