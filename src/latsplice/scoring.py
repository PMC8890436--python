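"""Splice-donor sequence models: position weight matrices and maximum-entropy
models with marginal constraints.

The donor model scores a 9-mer spanning the exon/intron boundary (by default
the last 3 exonic and first 6 intronic nucleotides, GT at intronic positions
1-2) as a log2 odds ratio against a background distribution.  The
maximum-entropy variant is the distribution of maximal Shannon entropy whose
marginals over chosen position subsets match the training data; with only
first-order (single-position) constraints it coincides with the PWM
independence model, while pairwise constraints capture adjacent-position
dependence in the donor consensus.
"""

from __future__ import annotations

import ast
import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: last 3 exonic + first 6 intronic nucleotides
DONOR_EXONIC = 3
DONOR_INTRONIC = 6
DONOR_K = DONOR_EXONIC + DONOR_INTRONIC


class ScoringError(ValueError):
    pass


def _encode(seq: str) -> tuple[int, ...]:
    try:
        return tuple(_BASE_INDEX[c] for c in seq.upper())
    except KeyError as exc:
        raise ScoringError(f"non-ACGT character in sequence {seq!r}") from exc


def default_constraint_sets(k: int) -> list[tuple[int, ...]]:
    """All singleton and adjacent-pair position subsets for a k-mer model."""
    singles = [(i,) for i in range(k)]
    pairs = [(i, i + 1) for i in range(k - 1)]
    return singles + pairs


@dataclass(frozen=True)
class ScoreThreshold:
    """Score cutoff in log2 units; ``inclusive`` controls whether equality passes."""

    value: float = 0.0
    inclusive: bool = True

    def passes(self, score: float) -> bool:
        if math.isnan(score):
            return False
        return score >= self.value if self.inclusive else score > self.value


@dataclass
class DonorSiteModel:
    """Probability model over donor k-mers plus a background distribution.

    ``probabilities`` and ``background`` are dense tensors of shape ``(4,)*k``
    indexed by base (A=0, C=1, G=2, T=3) at each position.
    """

    kind: str
    k: int
    probabilities: np.ndarray
    background: np.ndarray
    constraint_sets: list[tuple[int, ...]] = field(default_factory=list)
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = (4,) * self.k
        self.probabilities = np.asarray(self.probabilities, dtype=float).reshape(shape)
        self.background = np.asarray(self.background, dtype=float).reshape(shape)
        for name, arr in (("probabilities", self.probabilities), ("background", self.background)):
            if (arr < 0).any():
                raise ScoringError(f"{name} contains negative entries")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ScoringError(f"{name} does not sum to 1 (sum={arr.sum()!r})")

    def probability(self, seq: str) -> float:
        return float(self.probabilities[_encode(self._check_len(seq))])

    def background_probability(self, seq: str) -> float:
        return float(self.background[_encode(self._check_len(seq))])

    def _check_len(self, seq: str) -> str:
        if len(seq) != self.k:
            raise ScoringError(f"sequence length {len(seq)} != model k={self.k}")
        return seq

    # -- serialization ---------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the model as a plain-text ``kmer<TAB>prob`` table with header."""
        with open(path, "w") as fh:
            fh.write(f"#kind={self.kind}\n#k={self.k}\n")
            sets = ";".join(",".join(map(str, s)) for s in self.constraint_sets)
            fh.write(f"#constraint_sets={sets}\n")
            uniform = np.allclose(self.background, 0.25**self.k)
            fh.write(f"#background={'uniform' if uniform else 'explicit'}\n")
            for meta_key in sorted(self.fit_metadata):
                fh.write(f"#meta:{meta_key}={self.fit_metadata[meta_key]!r}\n")
            flat = self.probabilities.reshape(-1)
            bg = self.background.reshape(-1)
            for idx, kmer in enumerate(itertools.product(BASES, repeat=self.k)):
                line = f"{''.join(kmer)}\t{float(flat[idx])!r}"
                if not uniform:
                    line += f"\t{float(bg[idx])!r}"
                fh.write(line + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DonorSiteModel":
        header: dict[str, str] = {}
        meta: dict[str, object] = {}
        probs: list[float] = []
        bg: list[float] = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#meta:"):
                    key, _, val = line[6:].partition("=")
                    meta[key] = ast.literal_eval(val)
                elif line.startswith("#"):
                    key, _, val = line[1:].partition("=")
                    header[key] = val
                elif line:
                    parts = line.split("\t")
                    probs.append(float(parts[1]))
                    if len(parts) > 2:
                        bg.append(float(parts[2]))
        k = int(header["k"])
        sets = []
        if header.get("constraint_sets"):
            sets = [tuple(int(i) for i in s.split(",")) for s in header["constraint_sets"].split(";")]
        background = np.array(bg) if bg else np.full(4**k, 0.25**k)
        return cls(
            kind=header["kind"],
            k=k,
            probabilities=np.array(probs),
            background=background,
            constraint_sets=sets,
            fit_metadata=meta,
        )


def _validate_training(training_seqs: Sequence[str]) -> tuple[np.ndarray, int]:
    seqs = list(training_seqs)
    if not seqs:
        raise ScoringError("empty training set")
    k = len(seqs[0])
    if any(len(s) != k for s in seqs):
        raise ScoringError("training sequences have unequal lengths")
    return np.array([_encode(s) for s in seqs], dtype=np.intp), k


def fit_pwm(
    training_seqs: Sequence[str],
    pseudocount: float = 0.0,
    background: np.ndarray | None = None,
) -> DonorSiteModel:
    """Fit an independent per-position base-frequency model.

    Frequencies are ``(count + pseudocount) / (n + 4 * pseudocount)`` per
    position; a k-mer's probability is the product across positions.
    """
    if pseudocount < 0:
        raise ScoringError("pseudocount must be nonnegative")
    enc, k = _validate_training(training_seqs)
    n = enc.shape[0]
    freqs = np.empty((k, 4))
    for pos in range(k):
        counts = np.bincount(enc[:, pos], minlength=4).astype(float)
        freqs[pos] = (counts + pseudocount) / (n + 4 * pseudocount)
    probs = np.ones((4,) * k)
    for pos in range(k):
        shape = [1] * k
        shape[pos] = 4
        probs = probs * freqs[pos].reshape(shape)
    bg = np.full((4,) * k, 0.25**k) if background is None else background
    return DonorSiteModel(
        kind="pwm",
        k=k,
        probabilities=probs,
        background=bg,
        constraint_sets=[(i,) for i in range(k)],
        fit_metadata={"n_training": n, "pseudocount": pseudocount, "position_frequencies": freqs.tolist()},
    )


def _marginal(table: np.ndarray, positions: tuple[int, ...]) -> np.ndarray:
    # positions must be sorted ascending (normalized in fit_maxent)
    other = tuple(ax for ax in range(table.ndim) if ax not in positions)
    return table.sum(axis=other)


def _broadcast(marg: np.ndarray, positions: tuple[int, ...], k: int) -> np.ndarray:
    return marg.reshape([4 if i in positions else 1 for i in range(k)])


def fit_maxent(
    training_seqs: Sequence[str],
    constraint_sets: Iterable[Sequence[int]] | None = None,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> DonorSiteModel:
    """Fit the maximum-entropy distribution matching training marginals.

    The k-mer space (4^k states) is enumerated and the distribution of
    maximal entropy whose marginals over each ``constraint_sets`` entry match
    the (pseudocount-smoothed) training marginals is found by cyclic
    iterative scaling: each constrained marginal is matched exactly in turn
    until the largest discrepancy over all constraints falls below ``tol``.

    Target marginals are taken from the training distribution mixed with a
    uniform pseudo-mass of ``4 * pseudocount`` observations (so singleton
    marginal cells receive ``pseudocount`` each).  Smoothing the joint
    distribution once, rather than each marginal table separately, keeps
    the constraints mutually consistent while guaranteeing that no
    constrained marginal is zero.
    """
    enc, k = _validate_training(training_seqs)
    if constraint_sets is None:
        sets = default_constraint_sets(k)
    else:
        sets = [tuple(sorted(set(s))) for s in constraint_sets]
        if not sets or any(len(s) == 0 for s in sets):
            raise ScoringError("constraint sets must be non-empty position subsets")
        for s in sets:
            if any(p < 0 or p >= k for p in s):
                raise ScoringError(f"constraint set {s} out of range for k={k}")

    n = enc.shape[0]
    pseudo_mass = 4.0 * pseudocount
    targets: dict[tuple[int, ...], np.ndarray] = {}
    for s in sets:
        counts = np.zeros((4,) * len(s))
        for row in enc:
            counts[tuple(row[list(s)])] += 1
        counts += pseudo_mass / 4 ** len(s)
        targets[s] = counts / (n + pseudo_mass)

    p = np.full((4,) * k, 0.25**k)
    discrepancy = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for s, target in targets.items():
            current = _marginal(p, s)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(current > 0, target / np.where(current > 0, current, 1.0), 0.0)
            p = p * _broadcast(ratio, s, k)
        p /= p.sum()
        discrepancy = max(float(np.abs(_marginal(p, s) - t).max()) for s, t in targets.items())
        if discrepancy < tol:
            break
    else:
        warnings.warn(
            f"maxent fit did not converge in {max_iter} iterations; "
            f"max marginal discrepancy {discrepancy:.3e} (tol {tol:.1e})",
            RuntimeWarning,
            stacklevel=2,
        )

    bg = np.full((4,) * k, 0.25**k) if background is None else background
    return DonorSiteModel(
        kind="maxent",
        k=k,
        probabilities=p,
        background=bg,
        constraint_sets=sets,
        fit_metadata={
            "n_training": n,
            "pseudocount": pseudocount,
            "tol": tol,
            "iterations": iterations,
            "max_marginal_discrepancy": discrepancy,
        },
    )


def score_kmer(model: DonorSiteModel, seq: str) -> float:
    """log2 odds of the sequence under the model versus background.

    Returns ``-inf`` when the model assigns zero probability, so that the
    sequence fails any finite threshold.
    """
    p = model.probability(seq)
    q = model.background_probability(seq)
    if q <= 0:
        raise ScoringError(f"background probability is zero for {seq!r}")
    if p <= 0:
        return -math.inf
    return math.log2(p / q)
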