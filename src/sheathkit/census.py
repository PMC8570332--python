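"""Tail-contraction-state census from axial thickness profiles.

A whole-virion side view reduces to an axial profile: the apparent outer
diameter of the tail at each position z along its axis (z = 0 at the
head-proximal end, increasing toward the tip).  A non-contracted tail is
uniformly thick (the sheath covers the whole tail at ~240 A); a contracted
tail shows a thick contracted-sheath segment (~320 A) over roughly 45% of the
tail with the bare tube (~60 A) elsewhere.  This module classifies profiles
into {non_contracted, contracted x (near_head | middle | near_tip)}, tabulates
calls against the head DNA state, and computes the census percentages.  The
head state (DNA full / partial / empty) is an input label, not computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import NoSheathDetectedError

__all__ = [
    "HEAD_STATES",
    "TAIL_STATES",
    "AxialProfile",
    "TailStateCall",
    "TailStateTable",
    "CensusFraction",
    "classify_profile",
    "tabulate",
    "census_fractions",
    "simulate_profiles",
    "table1_counts",
]

HEAD_STATES = ("dna_full", "partial_dna", "empty")
TAIL_STATES = ("non_contracted", "near_head", "middle", "near_tip")

# phage G defaults: contracted sheath 320 A, bare tube ~60 A
DEFAULT_THICK_DIAM_ANG = 320.0
DEFAULT_THIN_DIAM_ANG = 60.0


@dataclass
class AxialProfile:
    """Per-position outer-diameter estimate along the tail axis."""

    z_ang: np.ndarray
    diameter_ang: np.ndarray
    tail_length_ang: float

    def __post_init__(self) -> None:
        self.z_ang = np.asarray(self.z_ang, dtype=np.float64)
        self.diameter_ang = np.asarray(self.diameter_ang, dtype=np.float64)
        if self.z_ang.ndim != 1 or self.z_ang.shape != self.diameter_ang.shape:
            raise ValueError("z and diameter must be 1D arrays of equal length")
        if np.any(np.diff(self.z_ang) <= 0):
            raise ValueError("z positions must be strictly increasing")
        if np.any(self.diameter_ang <= 0):
            raise ValueError("diameters must be > 0")
        if self.tail_length_ang <= 0:
            raise ValueError("tail_length_ang must be > 0")


@dataclass(frozen=True)
class TailStateCall:
    """Classification of one tail profile."""

    contraction: str  # non_contracted | contracted
    location: str  # near_head | middle | near_tip | not_applicable
    sheath_span_ang: Tuple[float, float]
    ambiguous: bool = False  # multiple disjoint thick runs; longest was used

    def __post_init__(self) -> None:
        if (self.location == "not_applicable") != (self.contraction == "non_contracted"):
            raise ValueError("location is not_applicable iff non_contracted")

    @property
    def tail_state(self) -> str:
        return "non_contracted" if self.contraction == "non_contracted" else self.location


@dataclass
class TailStateTable:
    """Head-state x tail-state count matrix (rows = head states)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts.reindex(index=list(HEAD_STATES), columns=list(TAIL_STATES))
        if df.isna().any().any():
            raise ValueError(
                f"counts must cover head states {HEAD_STATES} x tail states {TAIL_STATES}"
            )
        if (df.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = df.astype(int)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @classmethod
    def from_csv(cls, path) -> "TailStateTable":
        df = pd.read_csv(path).set_index("head_state")
        return cls(df)

    def to_csv(self, path) -> None:
        self.counts.rename_axis("head_state").to_csv(path)


def table1_counts() -> TailStateTable:
    """The packaged phage G cryo-EM census (364 particles)."""
    with resources.files("sheathkit.data").joinpath("table1_counts.csv").open() as fh:
        return TailStateTable.from_csv(fh)


def _thick_runs(above: np.ndarray) -> List[Tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs (stop exclusive)."""
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    return list(zip(edges[::2], edges[1::2]))


def classify_profile(
    p: AxialProfile,
    thick_diam_ang: float = DEFAULT_THICK_DIAM_ANG,
    thin_diam_ang: float = DEFAULT_THIN_DIAM_ANG,
    uniform_span_fraction: float = 0.9,
) -> TailStateCall:
    """Classify one axial profile as non-contracted or contracted-with-location.

    The profile is thresholded at the midpoint (thick + thin) / 2; the longest
    contiguous above-threshold run is the sheath span.  If the span covers at
    least ``uniform_span_fraction`` of the tail the call is non-contracted
    (uniform thickness); otherwise the call is contracted, located by the
    tercile of the tail containing the span centroid (head-proximal third ->
    near_head, central third -> middle, distal third -> near_tip).
    """
    if thick_diam_ang <= thin_diam_ang:
        raise ValueError("need thick_diam_ang > thin_diam_ang")
    threshold = (thick_diam_ang + thin_diam_ang) / 2.0
    above = p.diameter_ang > threshold
    runs = _thick_runs(above)
    if not runs:
        raise NoSheathDetectedError("no above-threshold sheath region in profile")
    ambiguous = len(runs) > 1
    start, stop = max(runs, key=lambda r: p.z_ang[r[1] - 1] - p.z_ang[r[0]])
    z0, z1 = float(p.z_ang[start]), float(p.z_ang[stop - 1])
    span = z1 - z0
    if span >= uniform_span_fraction * p.tail_length_ang:
        return TailStateCall("non_contracted", "not_applicable", (z0, z1), ambiguous)
    centroid = (z0 + z1) / 2.0
    tercile = centroid / p.tail_length_ang
    if tercile < 1.0 / 3.0:
        location = "near_head"
    elif tercile < 2.0 / 3.0:
        location = "middle"
    else:
        location = "near_tip"
    return TailStateCall("contracted", location, (z0, z1), ambiguous)


def tabulate(calls: Sequence[Tuple[str, TailStateCall]]) -> TailStateTable:
    """Count (head_state, call) pairs into the head x tail state table."""
    counts = pd.DataFrame(
        0, index=list(HEAD_STATES), columns=list(TAIL_STATES), dtype=int
    )
    for head_state, call in calls:
        if head_state not in HEAD_STATES:
            raise ValueError(f"unknown head state {head_state!r}")
        counts.loc[head_state, call.tail_state] += 1
    return TailStateTable(counts)


@dataclass(frozen=True)
class CensusFraction:
    """An exact fraction with its nearest-integer percentage."""

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def fraction(self) -> Optional[float]:
        return self.numerator / self.denominator if self.defined else None

    @property
    def percent(self) -> Optional[int]:
        return round(100.0 * self.numerator / self.denominator) if self.defined else None


def census_fractions(t: TailStateTable) -> Dict[str, CensusFraction]:
    """The census statistics: overall, by-location and by-head-state fractions.

    Location fractions are conditional on the contracted subset; the two
    head-state fractions are the contracted share among DNA-full heads and
    among partial + empty heads.  Undefined fractions (zero denominator) are
    returned as ``CensusFraction`` with ``defined == False``, never raised.
    """
    c = t.counts
    total = t.grand_total
    non_contracted = int(c["non_contracted"].sum())
    contracted = total - non_contracted
    by_loc = {loc: int(c[loc].sum()) for loc in ("near_head", "middle", "near_tip")}
    dna_full_total = int(c.loc["dna_full"].sum())
    dna_full_contracted = dna_full_total - int(c.loc["dna_full", "non_contracted"])
    rest_total = total - dna_full_total
    rest_contracted = contracted - dna_full_contracted
    return {
        "non_contracted": CensusFraction(non_contracted, total),
        "contracted": CensusFraction(contracted, total),
        "near_tip_of_contracted": CensusFraction(by_loc["near_tip"], contracted),
        "near_head_of_contracted": CensusFraction(by_loc["near_head"], contracted),
        "middle_of_contracted": CensusFraction(by_loc["middle"], contracted),
        "contracted_of_dna_full": CensusFraction(dna_full_contracted, dna_full_total),
        "contracted_of_partial_and_empty": CensusFraction(rest_contracted, rest_total),
    }


def _default_mixture() -> Dict[Tuple[str, str], float]:
    t = table1_counts()
    total = t.grand_total
    return {
        (h, s): t.counts.loc[h, s] / total for h in HEAD_STATES for s in TAIL_STATES
    }


def simulate_profiles(
    n: int,
    mixture: Optional[Dict[Tuple[str, str], float]] = None,
    noise_sigma_ang: float = 10.0,
    seed: int = 0,
    tail_length_ang: float = 4500.0,
    sheath_length_ang: float = 2040.0,
    uniform_diam_ang: float = 240.0,
    thick_diam_ang: float = DEFAULT_THICK_DIAM_ANG,
    thin_diam_ang: float = DEFAULT_THIN_DIAM_ANG,
    z_step_ang: float = 25.0,
) -> List[Tuple[str, AxialProfile]]:
    """Draw ``n`` synthetic (head_state, profile) pairs from a state mixture.

    The default mixture is the empirical joint distribution of the packaged
    phage G census; defaults for lengths/diameters are the phage G values
    (4500 A tail, 2040 A contracted sheath, 240 A uniform non-contracted
    diameter, 320/60 A contracted sheath/bare tube).  Diameters carry additive
    Gaussian jitter of ``noise_sigma_ang``.
    """
    mixture = mixture if mixture is not None else _default_mixture()
    keys = list(mixture)
    probs = np.array([mixture[k] for k in keys], dtype=np.float64)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture probabilities must be >= 0 and sum to 1")
    rng = np.random.default_rng(seed)
    z = np.arange(0.0, tail_length_ang + z_step_ang / 2.0, z_step_ang)
    spans = {
        "near_head": (0.0, sheath_length_ang),
        "middle": ((tail_length_ang - sheath_length_ang) / 2.0,
                   (tail_length_ang + sheath_length_ang) / 2.0),
        "near_tip": (tail_length_ang - sheath_length_ang, tail_length_ang),
    }
    out: List[Tuple[str, AxialProfile]] = []
    draws = rng.choice(len(keys), size=n, p=probs)
    for idx in draws:
        head_state, tail_state = keys[idx]
        if tail_state == "non_contracted":
            diam = np.full_like(z, uniform_diam_ang)
        else:
            z0, z1 = spans[tail_state]
            diam = np.where((z >= z0) & (z <= z1), thick_diam_ang, thin_diam_ang)
        diam = np.clip(diam + rng.normal(0.0, noise_sigma_ang, size=z.shape), 1.0, None)
        out.append((head_state, AxialProfile(z.copy(), diam, tail_length_ang)))
    return out
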