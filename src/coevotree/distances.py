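"""Pairwise genetic distances under the JTT model.

The distance between two aligned protein sequences is the maximum-likelihood
number of substitutions per site: the value of d >= 0 maximizing

    l(d) = sum_sites log( pi_a * [exp(Q d)]_{a,b} )

over the sites where both sequences have an unambiguous residue (pairwise
deletion).  Because JTT is reversible, l(d) is symmetric in the two
sequences, so distance(a, b) == distance(b, a) exactly.

Distances are clamped at a saturation cap (default 10 substitutions/site)
and flagged: beyond roughly 5-10 substitutions/site the likelihood surface
is essentially flat and the ML point estimate carries no information.

Column-bootstrap standard errors (resampling alignment columns with
replacement, the same columns for every pair) quantify the sampling
uncertainty of each pairwise estimate; they are reported alongside, and do
not feed into, the mirrortree point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from skbio import DistanceMatrix

from .alignment import ProteinAlignment
from .errors import InvalidParameterError, UncomputableDistanceError
from .jtt import JTTModel, N_STATES, encode_sequence, jtt_model

#: Default saturation cap, in expected substitutions per site.
DEFAULT_CAP = 10.0


@dataclass(frozen=True)
class MLDistance:
    """A single pairwise ML distance estimate."""

    distance: float
    saturated: bool
    n_sites: int  # comparable sites used (after pairwise deletion)


@dataclass(frozen=True)
class DistanceMatrixResult:
    """All-pairs genetic distances with saturation bookkeeping."""

    matrix: DistanceMatrix
    saturated_pairs: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class BootstrapSummary:
    """Per-pair standard errors from column-bootstrap replicates.

    ``standard_errors`` is a symmetric (n_taxa, n_taxa) array aligned with
    ``taxa``; ``skipped`` counts, per pair, replicates discarded because the
    resample left no comparable sites for that pair.
    """

    n_replicates: int
    taxa: tuple[str, ...]
    standard_errors: np.ndarray
    skipped: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.standard_errors, index=self.taxa, columns=self.taxa)


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """20x20 matrix of residue-pair counts over comparable sites."""
    mask = (a >= 0) & (b >= 0)
    codes = a[mask].astype(np.intp) * N_STATES + b[mask]
    return np.bincount(codes, minlength=N_STATES * N_STATES).reshape(N_STATES, N_STATES)


def _ml_distance_from_counts(counts: np.ndarray, model: JTTModel,
                             cap: float) -> tuple[float, bool]:
    n_diff = counts.sum() - np.trace(counts)
    if n_diff == 0:
        return 0.0, False
    # detailed balance makes pi_a P_ab == pi_b P_ba, so the symmetrized
    # counts give the same maximizer while making the objective exactly
    # invariant under swapping the two sequences
    counts = counts + counts.T
    log_pi = np.log(model.frequencies)
    nz = counts > 0
    weights = counts[nz]
    rows = np.nonzero(nz)[0]

    def neg_loglik(d: float) -> float:
        p = model.transition_matrix(d)
        with np.errstate(divide="ignore"):
            ll = log_pi[rows] + np.log(p[nz])
        ll[~np.isfinite(ll)] = -1e300
        return -float(weights @ ll)

    res = minimize_scalar(neg_loglik, bounds=(0.0, cap), method="bounded",
                          options={"xatol": 1e-8})
    d = float(res.x)
    # bounded search cannot touch the cap; treat estimates within sqrt(xatol)
    # of it as saturated and clamp
    if cap - d < 1e-4:
        return cap, True
    return d, False


def jtt_pairwise_distance(seq_a: str, seq_b: str,
                          model: JTTModel | None = None,
                          cap: float = DEFAULT_CAP,
                          labels: tuple[str, str] = ("seq_a", "seq_b")) -> MLDistance:
    """ML substitutions-per-site distance between two aligned sequences.

    Sites with a gap or ambiguous residue in either sequence are dropped
    (pairwise deletion).  Raises :class:`UncomputableDistanceError` if no
    comparable site remains.
    """
    if len(seq_a) != len(seq_b):
        raise InvalidParameterError("sequences must be aligned (equal length)")
    model = model or jtt_model()
    counts = _pair_counts(encode_sequence(seq_a), encode_sequence(seq_b))
    n_used = int(counts.sum())
    if n_used == 0:
        raise UncomputableDistanceError(*labels)
    d, saturated = _ml_distance_from_counts(counts, model, cap)
    return MLDistance(distance=d, saturated=saturated, n_sites=n_used)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing comparable sites (no multiple-hit correction).

    A monotone lower bound on the ML distance, used as a sanity oracle.
    """
    if len(seq_a) != len(seq_b):
        raise InvalidParameterError("sequences must be aligned (equal length)")
    counts = _pair_counts(encode_sequence(seq_a), encode_sequence(seq_b))
    total = counts.sum()
    if total == 0:
        raise UncomputableDistanceError("seq_a", "seq_b")
    return float((total - np.trace(counts)) / total)


def distance_matrix(aln: ProteinAlignment, model: JTTModel | None = None,
                    cap: float = DEFAULT_CAP) -> DistanceMatrixResult:
    """All unordered pairwise JTT ML distances for an alignment.

    Taxon order follows the alignment.  Raises on the first pair with no
    comparable sites, naming the pair.
    """
    model = model or jtt_model()
    enc = aln.encoded()
    n = aln.n_taxa
    out = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            counts = _pair_counts(enc[i], enc[j])
            if counts.sum() == 0:
                raise UncomputableDistanceError(aln.taxa[i], aln.taxa[j])
            d, sat = _ml_distance_from_counts(counts, model, cap)
            out[i, j] = out[j, i] = d
            if sat:
                saturated.append((aln.taxa[i], aln.taxa[j]))
    return DistanceMatrixResult(matrix=DistanceMatrix(out, ids=aln.taxa),
                                saturated_pairs=tuple(saturated))


def bootstrap_distances(aln: ProteinAlignment, model: JTTModel | None = None,
                        n_replicates: int = 1000, seed: int = 0,
                        cap: float = DEFAULT_CAP) -> BootstrapSummary:
    """Column-bootstrap standard errors for every pairwise distance.

    Each replicate resamples alignment columns with replacement (one column
    index draw shared by all pairs) and re-estimates every pairwise
    distance.  The standard error is the sample standard deviation of the
    replicate estimates (ddof=1; defined as 0 for a single replicate).
    Replicates in which a pair retains no comparable site are skipped for
    that pair and counted in ``skipped``.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    model = model or jtt_model()
    rng = np.random.default_rng(seed)
    enc = aln.encoded()
    n, length = aln.n_taxa, aln.length
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    # per-pair per-site pair codes; -1 marks non-comparable sites
    codes = {}
    for i, j in pairs:
        valid = (enc[i] >= 0) & (enc[j] >= 0)
        c = enc[i].astype(np.intp) * N_STATES + enc[j]
        c[~valid] = -1
        codes[i, j] = c

    reps = {p: [] for p in pairs}
    skipped = np.zeros((n, n), dtype=int)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        for i, j in pairs:
            c = codes[i, j][cols]
            c = c[c >= 0]
            if c.size == 0:
                skipped[i, j] += 1
                skipped[j, i] += 1
                continue
            counts = np.bincount(c, minlength=N_STATES * N_STATES)
            counts = counts.reshape(N_STATES, N_STATES)
            d, _ = _ml_distance_from_counts(counts, model, cap)
            reps[i, j].append(d)

    se = np.zeros((n, n))
    for i, j in pairs:
        vals = np.asarray(reps[i, j])
        se[i, j] = se[j, i] = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return BootstrapSummary(n_replicates=n_replicates, taxa=aln.taxa,
                            standard_errors=se, skipped=skipped)


# ---------------------------------------------------------------- I/O -----

def write_phylip(dm: DistanceMatrix, path) -> None:
    """Write a distance matrix in square PHYLIP format."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for taxon, row in zip(dm.ids, dm.data):
            fh.write(taxon + "  " + "  ".join(f"{v:.8f}" for v in row) + "\n")


def read_phylip(path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (labels up to first whitespace)."""
    with open(path) as fh:
        tokens = fh.read().split()
    if not tokens:
        raise InvalidParameterError(f"empty distance matrix file {path}")
    n = int(tokens[0])
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise InvalidParameterError(
            f"malformed PHYLIP matrix {path}: expected {expected} tokens, got {len(tokens)}")
    ids, rows = [], []
    k = 1
    for _ in range(n):
        ids.append(tokens[k])
        rows.append([float(x) for x in tokens[k + 1:k + 1 + n]])
        k += 1 + n
    return DistanceMatrix(np.asarray(rows), ids=ids)


def write_tidy_tsv(result: DistanceMatrixResult, path,
                   bootstrap: BootstrapSummary | None = None) -> None:
    """Write per-pair distances as tidy TSV (taxon_a, taxon_b, distance, se, saturated)."""
    dm = result.matrix
    sat = set(map(frozenset, result.saturated_pairs))
    rows = []
    for i, a in enumerate(dm.ids):
        for j in range(i + 1, len(dm.ids)):
            b = dm.ids[j]
            se = float(bootstrap.standard_errors[i, j]) if bootstrap is not None else np.nan
            rows.append({"taxon_a": a, "taxon_b": b, "distance": dm.data[i, j],
                         "se": se, "saturated": frozenset((a, b)) in sat})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
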