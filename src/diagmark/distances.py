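"""Pairwise evolutionary distances: p, JC69, K2P and T3P, with gamma rates.

Sites are compared under pairwise deletion: for each pair of sequences only
the columns where both carry an unambiguous base contribute. Transitions are
A<->G and C<->T; everything else among the four bases is a transversion.

The Tamura 3-parameter correction extends K2P with a GC-content term
h = 2*theta*(1-theta), theta being the mean G+C fraction of the two
sequences over their compared sites; at theta = 0.5 it reduces to K2P.

Gamma rate heterogeneity with shape ``a`` replaces each -ln(w) term by
a*(w**(-1/a) - 1), the standard rate-corrected form.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core_io import BASES, Alignment

logger = logging.getLogger(__name__)

MODELS = ("p", "jc69", "k2p", "t3p")
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturationWarning(UserWarning):
    pass


@dataclass(frozen=True)
class PairCounts:
    """Sufficient statistics for one sequence pair.

    L: compared sites; P, Q: transition and transversion proportions;
    theta: pooled G+C fraction of the two sequences over compared sites.
    """

    L: int
    P: float
    Q: float
    theta: float

    @property
    def p(self) -> float:
        """Total proportion of differing sites (p-distance)."""
        return self.P + self.Q


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over accessions."""

    labels: list[str]
    values: np.ndarray
    model: str
    gamma_shape: float | None = None
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    def write_phylip(self, path) -> None:
        """Lower-triangle PHYLIP-style text."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                vals = " ".join(f"{self.values[i, j]:.6f}" for j in range(i))
                fh.write(f"{lab:<12s} {vals}".rstrip() + "\n")


def pairwise_counts(seq_a: str, seq_b: str) -> PairCounts:
    """Count compared sites, transitions, transversions and pooled GC.

    Returns L = 0 (with P = Q = theta = NaN) when no column is comparable.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    L = ts = tv = gc = 0
    for ca, cb in zip(seq_a, seq_b):
        if ca not in BASES or cb not in BASES:
            continue
        L += 1
        gc += (ca in "GC") + (cb in "GC")
        if ca != cb:
            if (ca, cb) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if L == 0:
        return PairCounts(L=0, P=math.nan, Q=math.nan, theta=math.nan)
    return PairCounts(L=L, P=ts / L, Q=tv / L, theta=gc / (2 * L))


def _log_term(w: float, gamma_shape: float | None) -> float:
    """-ln(w), or its gamma-rate analogue a*(w^(-1/a) - 1); inf if w <= 0."""
    if w <= 0:
        return math.inf
    if gamma_shape is None:
        return -math.log(w)
    a = gamma_shape
    return a * (w ** (-1.0 / a) - 1.0)


def distance(counts: PairCounts, model: str, gamma_shape: float | None = None) -> float:
    """Model-corrected distance from pair counts.

    Returns ``inf`` on saturation (a log argument <= 0); callers flag and
    substitute rather than raising, so tree building stays possible.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if gamma_shape is not None and gamma_shape <= 0:
        raise ValueError("gamma shape must be positive")
    if counts.L == 0:
        raise ValueError("no compared sites for this pair")

    P, Q = counts.P, counts.Q
    p = counts.p
    if model == "p":
        if gamma_shape is not None:
            logger.warning("gamma correction has no p-distance form; ignored")
        return p
    if model == "jc69":
        return 0.75 * _log_term(1.0 - (4.0 / 3.0) * p, gamma_shape)
    if model == "k2p":
        return (0.5 * _log_term(1.0 - 2.0 * P - Q, gamma_shape)
                + 0.25 * _log_term(1.0 - 2.0 * Q, gamma_shape))
    # t3p
    theta = counts.theta
    h = 2.0 * theta * (1.0 - theta)
    if h == 0:
        # no GC heterozygosity: the P term degenerates; fall back to K2P form
        logger.warning("T3P with h=0 (theta in {0,1}); using K2P form")
        return distance(counts, "k2p", gamma_shape)
    return (h * _log_term(1.0 - P / h - Q, gamma_shape)
            + 0.5 * (1.0 - h) * _log_term(1.0 - 2.0 * Q, gamma_shape))


def distance_matrix(alignment: Alignment, model: str = "k2p",
                    gamma_shape: float | None = None) -> DistanceMatrix:
    """All pairwise distances under ``model`` with pairwise deletion.

    Saturated pairs receive twice the largest finite distance and are listed
    in ``saturated_pairs``. A pair with zero compared sites is an error.
    """
    n = alignment.n_sequences
    if n < 2:
        raise ValueError("distance matrix needs >= 2 sequences")
    labels = list(alignment.accessions)
    values = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i, j in itertools.combinations(range(n), 2):
        counts = pairwise_counts(alignment.sequences[i], alignment.sequences[j])
        if counts.L == 0:
            raise ValueError(
                f"no comparable site between {labels[i]!r} and {labels[j]!r}")
        d = distance(counts, model, gamma_shape)
        if math.isinf(d):
            saturated.append((labels[i], labels[j]))
            d = math.nan  # placeholder, replaced below
        values[i, j] = values[j, i] = d

    if saturated:
        finite = values[np.isfinite(values)]
        fill = 2.0 * float(finite.max()) if finite.size else 2.0
        for a, b in saturated:
            i, j = labels.index(a), labels.index(b)
            values[i, j] = values[j, i] = fill
        logger.warning("saturated pairs replaced with %g: %s", fill, saturated)

    return DistanceMatrix(labels=labels, values=values, model=model,
                          gamma_shape=gamma_shape, saturated_pairs=saturated)
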