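"""Robustness analyses: hypersphere-surface sampling around the most central
optimal learner, and perturbations of connectivity, initial weights, and the
learning rate.

The hypersphere sweep works in a standardized 4-D parameter space where each
coordinate is measured in units of that parameter's grid range (max − min)
and the central optimal learner sits at the origin. Points are sampled
uniformly from the sphere surface of radius r (independent Gaussians scaled
to norm r), mapped back to original units, and scored by an indicator: 1 iff
the combination passes all optimal-learner criteria and ties the center's
SOC performance within ε_soc. De-standardized samples may leave the searched
box or go negative; they are not clipped — parameter combinations that are
nonsensical (negative weights or rates) simply score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import circuit, gridsearch
from .gridsearch import OptimalLearnerCriteria, batch_evaluate
from .odors import generate_odor_library
from .params import (GRID_BOUNDS, ConfigurationError, free_parameters,
                     make_params, parameter_ranges, reference_optimum)
from .protocol import ProtocolSpec, run_foc_soc_protocol
from .seeding import spawn_rng


def sample_hypersphere_surface(center: np.ndarray, r: float, n: int = 700,
                               rng: np.random.Generator | int = 0) -> np.ndarray:
    """``n`` points uniform on the surface of the 4-D sphere of radius ``r``
    around ``center`` (standardized coordinates).

    Draws independent standard Gaussians (σ = 1; any σ > 0 gives the same
    surface law) and scales each vector to norm ``r``. With ``r = 0`` every
    sample equals the center.
    """
    if r < 0 or n < 1:
        raise ConfigurationError("need r >= 0 and n >= 1")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    center = np.asarray(center, float)
    g = rng.standard_normal((n, center.size))
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    norms[norms == 0] = 1.0  # astronomically unlikely; keeps the map total
    return center + r * g / norms


def destandardize(points: np.ndarray, center_values: np.ndarray,
                  ranges: np.ndarray) -> np.ndarray:
    """Map standardized offsets to original units: value = center + u·range."""
    ranges = np.asarray(ranges, float)
    if np.any(ranges < 0):
        raise ConfigurationError("parameter ranges must be non-negative")
    return np.asarray(center_values, float) + np.asarray(points, float) * ranges


def standardize(values: np.ndarray, center_values: np.ndarray,
                ranges: np.ndarray) -> np.ndarray:
    """Inverse of :func:`destandardize` (zero-range coordinates map to 0)."""
    ranges = np.asarray(ranges, float)
    safe = np.where(ranges > 0, ranges, 1.0)
    out = (np.asarray(values, float) - np.asarray(center_values, float)) / safe
    return np.where(ranges > 0, out, 0.0)


def indicator_optimal(model_id: str, combo: dict[str, float],
                      criteria: OptimalLearnerCriteria,
                      reference_soc: float) -> int:
    """1 iff ``combo`` passes all criteria and ties ``reference_soc`` within
    ε_soc; combos with any negative parameter score 0."""
    if any(v < 0 for v in combo.values()):
        return 0
    res = gridsearch.evaluate_combination(model_id, combo, criteria,
                                          engine="reduced")
    return int(res.passes and abs(res.soc_bias - reference_soc) <= criteria.epsilon_soc)


def _indicator_batch(model_id: str, names, values: np.ndarray,
                     criteria: OptimalLearnerCriteria,
                     reference_soc: float) -> np.ndarray:
    sensible = np.all(values >= 0, axis=1)
    out = np.zeros(values.shape[0], dtype=bool)
    if sensible.any():
        combos = {n: values[sensible, i] for i, n in enumerate(names)}
        res = batch_evaluate(model_id, combos, criteria)
        out[sensible] = res["passes"] & (
            np.abs(res["soc_bias"] - reference_soc) <= criteria.epsilon_soc)
    return out.astype(int)


def radius_sweep(model_id: str, center: dict[str, float] | None = None,
                 criteria: OptimalLearnerCriteria = OptimalLearnerCriteria(),
                 radii: np.ndarray | None = None, n_per_radius: int = 700,
                 seed: int = 999, reference_soc: float | None = None,
                 indicator=None) -> pd.DataFrame:
    """Fraction of optimal samples on hypersphere surfaces of growing radius.

    ``center`` defaults to the motif's reference optimum. ``indicator`` can
    replace the model evaluation with a synthetic scorer
    ``f(values (n,4)) -> {0,1} array`` (used to validate the machinery).
    """
    if center is None:
        center = reference_optimum(model_id)
    names = free_parameters(model_id)
    center_vec = np.array([center[n] for n in names])
    ranges = parameter_ranges(model_id)
    if radii is None:
        radii = np.linspace(0.0, 1.0, 100)
    if reference_soc is None and indicator is None:
        reference_soc = gridsearch.evaluate_combination(
            model_id, center, criteria, engine="reduced").soc_bias
    rows = []
    for i, r in enumerate(np.asarray(radii, float)):
        rng = spawn_rng(seed, "hypersphere", i)
        offsets = sample_hypersphere_surface(np.zeros(len(names)), r,
                                             n_per_radius, rng)
        values = destandardize(offsets, center_vec, ranges)
        if indicator is not None:
            flags = np.asarray(indicator(values), int)
        else:
            flags = _indicator_batch(model_id, names, values, criteria,
                                     reference_soc)
        rows.append({"model": model_id, "r": float(r), "n_samples": n_per_radius,
                     "fraction_optimal": float(flags.mean()), "seed": seed})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# perturbation experiments

_PERTURBATION_KINDS = ("connectivity", "init_weight", "learning_rate")


def _run_perturbed(params, library, spec, w_plus=None, w_minus=None,
                   extension=False):
    state = circuit.initial_state(params, w_plus=w_plus, w_minus=w_minus)
    return run_foc_soc_protocol(params, library, spec, state=state)


def _collect(result, model_id, kind, instance, drawn) -> list[dict]:
    rows = []
    for phase in ("post_FOC", "post_SOC"):
        for odor in (1, 2):
            rows.append({"model": model_id, "kind": kind, "instance": instance,
                         "drawn_value": drawn, "phase": phase, "odor": odor,
                         "bias": result.bias(phase, odor)})
    return rows


def draw_connectivity_weights(rng: np.random.Generator, n_kc: int,
                              fraction: float, init_plus: float,
                              init_minus: float) -> tuple[np.ndarray, np.ndarray]:
    """KC>MBON weight vectors retaining exactly ``round(fraction·n_kc)``
    synapses per MBON (independent subsets, identical counts); severed
    synapses are 0 and, with clamped depression, stay 0."""
    keep = round(fraction * n_kc)
    out = []
    for init in (init_plus, init_minus):
        vec = np.zeros(n_kc)
        vec[rng.choice(n_kc, size=keep, replace=False)] = init
        out.append(vec)
    return out[0], out[1]


def perturb_connectivity(model_id: str, n_instances: int = 100,
                         fraction_range: tuple[float, float] = (0.25, 1.0),
                         seed: int = 999, combo: dict[str, float] | None = None,
                         spec: ProtocolSpec = ProtocolSpec()) -> pd.DataFrame:
    """Random KC>MBON subsampling: per instance draw one retention fraction,
    keep that many synapses (independently chosen per MBON, identical
    counts), zero the rest, and run the full protocol.

    Severed synapses stay at weight 0 throughout (depression is clamped at
    zero), so they contribute to neither rates nor plasticity.
    """
    lo, hi = fraction_range
    if not (0 < lo <= hi <= 1):
        raise ConfigurationError("fraction range must lie within (0, 1]")
    params = make_params(model_id, combo)
    library = generate_odor_library(n_kc=params.n_kc, seed=seed)
    rows = []
    for i in range(n_instances):
        rng = spawn_rng(seed, "connectivity", i)
        frac = float(rng.uniform(lo, hi))
        w_plus, w_minus = draw_connectivity_weights(
            rng, params.n_kc, frac,
            params.init_kc_mbon_plus, params.init_kc_mbon_minus)
        result = _run_perturbed(params, library, spec, w_plus=w_plus,
                                w_minus=w_minus)
        rows += _collect(result, model_id, "connectivity", i, frac)
    return pd.DataFrame(rows)


def perturb_init_weights(model_id: str, jitter: float = 0.05,
                         n_instances: int = 100, seed: int = 999,
                         combo: dict[str, float] | None = None,
                         spec: ProtocolSpec = ProtocolSpec()) -> pd.DataFrame:
    """Full connectivity, every KC>MBON weight i.i.d. uniform within
    ±``jitter`` of the default initial value."""
    if jitter < 0:
        raise ConfigurationError("jitter must be >= 0")
    params = make_params(model_id, combo)
    library = generate_odor_library(n_kc=params.n_kc, seed=seed)
    rows = []
    for i in range(n_instances):
        rng = spawn_rng(seed, "init_weight", i)
        factors = rng.uniform(1 - jitter, 1 + jitter, size=(2, params.n_kc))
        result = _run_perturbed(params, library, spec,
                                w_plus=factors[0] * params.init_kc_mbon_plus,
                                w_minus=factors[1] * params.init_kc_mbon_minus)
        rows += _collect(result, model_id, "init_weight", i, jitter)
    return pd.DataFrame(rows)


def perturb_learning_rate(model_id: str,
                          alpha_range: tuple[float, float] | None = None,
                          n_instances: int = 100, seed: int = 999,
                          combo: dict[str, float] | None = None,
                          spec: ProtocolSpec = ProtocolSpec()) -> pd.DataFrame:
    """Draw the KC>MBON⁻ learning rate uniformly from the screened range
    (grid min to max by default) per instance."""
    if alpha_range is None:
        alpha_range = GRID_BOUNDS[model_id]["alpha_kc_mbon_minus"]
    lo, hi = alpha_range
    if not (0 <= lo <= hi):
        raise ConfigurationError("invalid learning-rate range")
    base = make_params(model_id, combo)
    library = generate_odor_library(n_kc=base.n_kc, seed=seed)
    rows = []
    for i in range(n_instances):
        rng = spawn_rng(seed, "learning_rate", i)
        alpha = float(rng.uniform(lo, hi))
        params = base.with_updates(alpha_kc_mbon_minus=alpha)
        result = _run_perturbed(params, library, spec)
        rows += _collect(result, model_id, "learning_rate", i, alpha)
    return pd.DataFrame(rows)


def perturb(kind: str, model_id: str, **kwargs) -> pd.DataFrame:
    if kind not in _PERTURBATION_KINDS:
        raise ConfigurationError(f"unknown perturbation kind {kind!r}")
    fn = {"connectivity": perturb_connectivity,
          "init_weight": perturb_init_weights,
          "learning_rate": perturb_learning_rate}[kind]
    return fn(model_id, **kwargs)


def summarize_perturbation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD of the biases per (model, kind, phase, odor)."""
    g = table.groupby(["model", "kind", "phase", "odor"])["bias"]
    return g.agg(["mean", "std", "count"]).reset_index()
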