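"""Sparse Kenyon-cell odor codes with controlled overlap, and compound
stimuli for second-order conditioning.

Each elementary odor is a binary activity pattern over the Kenyon-cell (KC)
population: 10% of the 2000 KCs fire at 3 Hz, the rest stay at the 0 Hz
baseline. Odor 1 is drawn uniformly; odors 2 and 3 are drawn sequentially,
taking any mandated overlap KCs as a random subset of the earlier pattern and
the remainder from so-far unused KCs, so realized pairwise intersection sizes
are exact (``round(overlap × pattern_size)``).

The joint odor-1+odor-2 presentation used during second-order conditioning
("subsampled" compound) keeps a random 50% of each parent's representation so
the total number of active KCs matches a single odor; the "additive" control
activates the full union. For overlapping parents the 50% subsample is drawn
stratified over {shared, private-to-a, private-to-b}, which reproduces both
reference counts: 200 active KCs for disjoint 200-KC parents and 150 at 50%
overlap.

Indices are 0-based throughout; serialized output states the convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import (ACTIVATION_FRACTION, ConfigurationError, KC_BASELINE,
                     MASTER_SEED, N_KC, ODOR_ACTIVATION)

COMPOUND_MODES = ("subsampled", "additive")


def _as_index_array(indices, n_kc: int) -> np.ndarray:
    idx = np.asarray(sorted(indices), dtype=np.int64)
    if idx.size and (idx[0] < 0 or idx[-1] >= n_kc):
        raise ConfigurationError("KC index out of range")
    if np.unique(idx).size != idx.size:
        raise ConfigurationError("duplicate KC indices")
    return idx


@dataclass(frozen=True)
class OdorPattern:
    """One odor: the set of active KC indices and their drive rate (Hz)."""

    id: object
    active_indices: np.ndarray
    drive: float = ODOR_ACTIVATION

    @property
    def size(self) -> int:
        return int(self.active_indices.size)

    def overlap_with(self, other: "OdorPattern") -> int:
        return int(np.intersect1d(self.active_indices, other.active_indices).size)


@dataclass(frozen=True)
class CompoundStimulus:
    """Joint presentation of two odors (50%-subsampled or additive union)."""

    mode: str
    parents: tuple
    active_indices: np.ndarray
    drive: float = ODOR_ACTIVATION

    @property
    def size(self) -> int:
        return int(self.active_indices.size)


@dataclass(frozen=True)
class OdorLibrary:
    """Three odors over one KC population, with exact pairwise overlaps."""

    n_kc: int
    patterns: dict
    overlap_spec: dict = field(default_factory=dict)
    seed: int = MASTER_SEED

    def pattern(self, odor: int) -> OdorPattern:
        return self.patterns[odor]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "mbsoc odor library; KC indices are 0-based",
            "n_kc": self.n_kc,
            "seed": self.seed,
            "overlap_spec": {f"{a}-{b}": v for (a, b), v in self.overlap_spec.items()},
            "odors": {
                str(k): {"drive": p.drive, "active_indices": p.active_indices.tolist()}
                for k, p in self.patterns.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "OdorLibrary":
        payload = json.loads(Path(path).read_text())
        patterns = {
            int(k): OdorPattern(int(k), _as_index_array(v["active_indices"], payload["n_kc"]),
                                float(v["drive"]))
            for k, v in payload["odors"].items()
        }
        overlap = {tuple(int(x) for x in k.split("-")): v
                   for k, v in payload.get("overlap_spec", {}).items()}
        return cls(n_kc=payload["n_kc"], patterns=patterns,
                   overlap_spec=overlap, seed=payload.get("seed", MASTER_SEED))


def _overlap_count(overlap_spec: dict, a: int, b: int, pattern_size: int) -> int:
    v = overlap_spec.get((a, b), overlap_spec.get((b, a), 0.0))
    if not 0.0 <= v <= 1.0:
        raise ConfigurationError("overlap fractions must lie in [0, 1]")
    # round-half-to-even, matching the pattern-size rounding
    return round(v * pattern_size)


def generate_odor_library(n_kc: int = N_KC,
                          activation_fraction: float = ACTIVATION_FRACTION,
                          overlap_spec: dict | None = None,
                          seed: int = MASTER_SEED) -> OdorLibrary:
    """Draw the three-odor library used by the conditioning experiments.

    ``overlap_spec`` maps odor pairs, e.g. ``{(1, 2): 0.5}``, to target
    overlaps as fractions of the pattern size; realized intersection sizes
    are exact. Unlisted pairs are disjoint.

    Raises :class:`ConfigurationError` if the requested sizes/overlaps cannot
    be packed into ``n_kc`` cells.
    """
    if not 0.0 <= activation_fraction <= 1.0:
        raise ConfigurationError("activation_fraction must lie in [0, 1]")
    overlap_spec = dict(overlap_spec or {})
    size = round(activation_fraction * n_kc)
    rng = np.random.default_rng(seed)
    all_kcs = np.arange(n_kc)

    p1 = rng.choice(all_kcs, size=size, replace=False)

    k12 = _overlap_count(overlap_spec, 1, 2, size)
    unused = np.setdiff1d(all_kcs, p1, assume_unique=False)
    if size - k12 > unused.size:
        raise ConfigurationError("odor 2 does not fit: too few unused KCs")
    p2 = np.concatenate([
        rng.choice(p1, size=k12, replace=False) if k12 else np.empty(0, dtype=np.int64),
        rng.choice(unused, size=size - k12, replace=False) if size - k12 else np.empty(0, dtype=np.int64),
    ])

    k31 = _overlap_count(overlap_spec, 3, 1, size)
    k32 = _overlap_count(overlap_spec, 3, 2, size)
    only1 = np.setdiff1d(p1, p2)
    only2 = np.setdiff1d(p2, p1)
    if k31 > only1.size or k32 > only2.size or k31 + k32 > size:
        raise ConfigurationError("infeasible overlap specification for odor 3")
    unused3 = np.setdiff1d(all_kcs, np.union1d(p1, p2))
    rest = size - k31 - k32
    if rest > unused3.size:
        raise ConfigurationError("odor 3 does not fit: too few unused KCs")
    p3 = np.concatenate([
        rng.choice(only1, size=k31, replace=False) if k31 else np.empty(0, dtype=np.int64),
        rng.choice(only2, size=k32, replace=False) if k32 else np.empty(0, dtype=np.int64),
        rng.choice(unused3, size=rest, replace=False) if rest else np.empty(0, dtype=np.int64),
    ])

    patterns = {i: OdorPattern(i, _as_index_array(p, n_kc))
                for i, p in ((1, p1), (2, p2), (3, p3))}
    return OdorLibrary(n_kc=n_kc, patterns=patterns,
                       overlap_spec=overlap_spec, seed=seed)


def make_compound(a: OdorPattern, b: OdorPattern, mode: str = "subsampled",
                  seed: int | np.random.Generator = 0) -> CompoundStimulus:
    """Joint presentation of two odors.

    ``additive``: the exact union of both patterns. ``subsampled``: a
    stratified 50% draw — half of the shared KCs plus half of each parent's
    private KCs, each count rounded half-to-even.
    """
    if mode not in COMPOUND_MODES:
        raise ConfigurationError(f"unknown compound mode {mode!r}")
    if a.drive != b.drive:
        raise ConfigurationError("compound parents must share a drive rate")
    union = np.union1d(a.active_indices, b.active_indices)
    if mode == "additive":
        idx = union
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        shared = np.intersect1d(a.active_indices, b.active_indices)
        only_a = np.setdiff1d(a.active_indices, shared)
        only_b = np.setdiff1d(b.active_indices, shared)
        parts = []
        for pool in (shared, only_a, only_b):
            k = round(0.5 * pool.size)
            if k:
                parts.append(rng.choice(pool, size=k, replace=False))
        idx = np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
    return CompoundStimulus(mode=mode, parents=(a.id, b.id),
                            active_indices=idx.astype(np.int64), drive=a.drive)


def kc_drive(stimulus: OdorPattern | CompoundStimulus, n_kc: int) -> np.ndarray:
    """Dense KC rate vector (Hz): ``drive`` on active cells, baseline elsewhere."""
    if stimulus.active_indices.size and (
            stimulus.active_indices.min() < 0 or stimulus.active_indices.max() >= n_kc):
        raise ConfigurationError("stimulus indices out of range for this KC population")
    rates = np.full(n_kc, KC_BASELINE, dtype=float)
    rates[stimulus.active_indices] = stimulus.drive
    return rates
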