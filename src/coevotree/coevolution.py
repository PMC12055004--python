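"""Mirrortree correlation and Fisher r-to-z comparison of gene pairs.

The mirrortree statistic treats the strict upper triangles of two gene
families' pairwise distance matrices, restricted to their common organisms
and ordered identically (alphabetically), as paired observations
(R_i, S_i), i = 1..N(N-1)/2, and computes the Pearson correlation

    r = sum_i (R_i - Rbar)(S_i - Sbar)
        / sqrt( sum_i (R_i - Rbar)^2 * sum_i (S_i - Sbar)^2 ).

A high r indicates that the two families' evolutionary rates covary along
the shared species history.  Correlations are compared through Fisher's
r-to-z transformation r' = 1/2 ln|(1+r)/(1-r)| (equivalently atanh r),
which is approximately normal with variance 1/(N-3) where N is the number
of common organisms, giving the two-correlation z statistic

    z = (r'_1 - r'_2) / sqrt( 1/(N_1 - 3) + 1/(N_2 - 3) ).

Two sign conventions are supported: ``"equation"`` returns z exactly as
above; ``"negated"`` flips the sign so a larger first correlation yields a
negative z (some reports quote the statistic that way round).  The p-value
is a standard-normal tail probability, two-sided by default.

Note that because both gene families evolve along the same species tree,
the mirrortree r is positive even for functionally unrelated genes; this
baseline inflation is why target pairs are judged against control-gene
panels and an empirical cutoff (0.8 by convention) rather than against
r = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .errors import (DegenerateSampleSizeError, InsufficientOverlapError,
                     InvalidParameterError, UndefinedCorrelationError)

#: Control panels conventionally used alongside a target pair: conserved
#: housekeeping genes and lipid-metabolism enzymes.
HOUSEKEEPING_CONTROLS = ("GAPDH", "PGK1", "ACT1", "HSP60", "CYTC", "TPI1",
                         "CDC42", "RPL5")
LIPID_METABOLISM_CONTROLS = ("DGA1", "DGK1", "LRO1", "TGL3", "FAA1", "LCB1",
                             "ERG4")

#: Empirical mirrortree cutoff below which a correlation is not called.
DEFAULT_CUTOFF = 0.8

_MIN_TAXA = 4  # Fisher variance 1/(N-3) degenerates below this


@dataclass(frozen=True)
class CorrelationResult:
    """A mirrortree Pearson correlation with its Fisher transform."""

    r: float
    n_taxa: int
    gene_pair: tuple[str, str] = ("gene_a", "gene_b")

    @property
    def n_pairs(self) -> int:
        return self.n_taxa * (self.n_taxa - 1) // 2

    @property
    def r_fisher(self) -> float:
        if abs(self.r) >= 1.0:
            return math.copysign(math.inf, self.r)
        return fisher_transform(self.r)


@dataclass(frozen=True)
class ZComparison:
    """z statistic contrasting two mirrortree correlations."""

    z: float
    p_value: float
    n1: int
    n2: int
    pair_1: tuple[str, str]
    pair_2: tuple[str, str]
    sign_convention: str = "equation"


def common_taxa_align(dm1: DistanceMatrix, dm2: DistanceMatrix,
                      ) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Restrict both matrices to their common taxa, alphabetically ordered.

    Raises :class:`InsufficientOverlapError` if fewer than four taxa are
    shared (the Fisher variance 1/(N-3) is degenerate below that).
    """
    common = sorted(set(dm1.ids) & set(dm2.ids))
    if len(common) < _MIN_TAXA:
        raise InsufficientOverlapError(
            f"only {len(common)} common taxa (need >= {_MIN_TAXA}): {common}")
    return dm1.filter(common), dm2.filter(common)


def mirrortree_correlation(dm1: DistanceMatrix, dm2: DistanceMatrix,
                           gene_pair: tuple[str, str] = ("gene_a", "gene_b"),
                           ) -> CorrelationResult:
    """Pearson correlation of the two matrices' strict upper triangles.

    The matrices are first restricted to their common taxa and sorted
    alphabetically, so entries pair up organism-for-organism.  Symmetric in
    its arguments.  Raises :class:`UndefinedCorrelationError` when either
    triangle has zero variance.
    """
    a, b = common_taxa_align(dm1, dm2)
    x, y = a.condensed_form(), b.condensed_form()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in distances for pair {gene_pair}")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    return CorrelationResult(r=r, n_taxa=len(a.ids), gene_pair=gene_pair)


def fisher_transform(r: float) -> float:
    """Fisher's r-to-z: r' = 1/2 ln|(1+r)/(1-r)| (= atanh r on (-1, 1))."""
    if not -1.0 < r < 1.0:
        raise InvalidParameterError(
            f"Fisher transform requires |r| < 1, got r={r}")
    return float(np.arctanh(r))


def inverse_fisher_transform(z: float) -> float:
    """Inverse of :func:`fisher_transform` (tanh)."""
    return float(np.tanh(z))


def compare_correlations(c1: CorrelationResult, c2: CorrelationResult,
                         sign_convention: str = "equation",
                         two_sided: bool = True) -> ZComparison:
    """z test for the difference of two mirrortree correlations.

    ``sign_convention="equation"`` gives z = (r'1 - r'2) / SE;
    ``"negated"`` negates it so the larger first correlation scores negative.
    """
    if sign_convention not in ("equation", "negated"):
        raise InvalidParameterError(
            f"sign_convention must be 'equation' or 'negated', got {sign_convention!r}")
    for c in (c1, c2):
        if c.n_taxa < _MIN_TAXA:
            raise DegenerateSampleSizeError(
                f"pair {c.gene_pair}: N={c.n_taxa} < {_MIN_TAXA}, "
                "Fisher variance 1/(N-3) degenerate")
    se = math.sqrt(1.0 / (c1.n_taxa - 3) + 1.0 / (c2.n_taxa - 3))
    z = (c1.r_fisher - c2.r_fisher) / se
    if sign_convention == "negated":
        z = -z
    if math.isnan(z):  # both transforms infinite with equal sign
        z = 0.0
    if two_sided:
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = float(stats.norm.sf(z))
    return ZComparison(z=z, p_value=p, n1=c1.n_taxa, n2=c2.n_taxa,
                       pair_1=c1.gene_pair, pair_2=c2.gene_pair,
                       sign_convention=sign_convention)


@dataclass(frozen=True)
class ControlPanelReport:
    """Target correlation judged against a panel of control correlations."""

    target: CorrelationResult
    table: pd.DataFrame
    cutoff: float

    @property
    def target_above_cutoff(self) -> bool:
        return self.target.r > self.cutoff


def control_panel_analysis(target: CorrelationResult,
                           controls: Sequence[CorrelationResult],
                           cutoff: float = DEFAULT_CUTOFF,
                           sign_convention: str = "equation",
                           two_sided: bool = True,
                           bh_correct: bool = False) -> ControlPanelReport:
    """Compare a target correlation against each control correlation.

    One row per control: its label, r, r', N, the z statistic of target vs
    control and the associated p-value.  Rows whose comparison fails (e.g.
    too few taxa) are flagged in the ``error`` column and the run
    continues.  ``bh_correct`` adds Benjamini-Hochberg adjusted p-values
    (off by default).
    """
    if not controls:
        raise InvalidParameterError("need at least one control correlation")
    if not 0.0 < cutoff < 1.0:
        raise InvalidParameterError(f"cutoff must be in (0, 1), got {cutoff}")
    rows = []
    for ctrl in controls:
        row = {"control": "-".join(ctrl.gene_pair), "r": ctrl.r,
               "r_fisher": ctrl.r_fisher, "n_taxa": ctrl.n_taxa,
               "z_vs_target": np.nan, "p": np.nan, "error": ""}
        try:
            cmp = compare_correlations(target, ctrl,
                                       sign_convention=sign_convention,
                                       two_sided=two_sided)
            row["z_vs_target"] = cmp.z
            row["p"] = cmp.p_value
        except DegenerateSampleSizeError as exc:
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    if bh_correct:
        ok = table["p"].notna()
        adjusted = np.full(len(table), np.nan)
        if ok.any():
            adjusted[ok.to_numpy()] = stats.false_discovery_control(
                table.loc[ok, "p"].to_numpy())
        table["p_bh"] = adjusted
    return ControlPanelReport(target=target, table=table, cutoff=cutoff)


# ---------------------------------------------- phylogenetic profiling -----

@dataclass(frozen=True)
class PresenceAbsenceProfile:
    """Binary presence/absence calls for one gene family across taxa."""

    gene: str
    calls: Mapping[str, bool]

    def __post_init__(self):
        if not self.calls:
            raise InvalidParameterError(f"profile {self.gene!r} has no taxa")
        object.__setattr__(
            self, "calls", {str(t): bool(v) for t, v in self.calls.items()})

    @property
    def present_taxa(self) -> frozenset:
        return frozenset(t for t, v in self.calls.items() if v)


@dataclass(frozen=True)
class CooccurrenceResult:
    """Agreement between two presence/absence profiles."""

    jaccard: float
    co_presence: int
    n_shared_taxa: int
    p_value: float
    gene_pair: tuple[str, str]


def profile_cooccurrence(p1: PresenceAbsenceProfile,
                         p2: PresenceAbsenceProfile) -> CooccurrenceResult:
    """Jaccard agreement of presence calls plus a hypergeometric tail test.

    Profiles are restricted to their shared taxon set.  The p-value is the
    probability of observing at least the seen co-presence count if gene 2's
    presences were placed uniformly at random given both genes' marginal
    presence counts (hypergeometric upper tail).
    """
    shared = sorted(set(p1.calls) & set(p2.calls))
    if not shared:
        raise InsufficientOverlapError(
            f"profiles {p1.gene!r} and {p2.gene!r} share no taxa")
    a = {t for t in shared if p1.calls[t]}
    b = {t for t in shared if p2.calls[t]}
    union, inter = a | b, a & b
    jaccard = len(inter) / len(union) if union else float("nan")
    m, big_k, n, k = len(shared), len(a), len(b), len(inter)
    p = float(stats.hypergeom.sf(k - 1, m, big_k, n)) if union else 1.0
    return CooccurrenceResult(jaccard=jaccard, co_presence=k,
                              n_shared_taxa=m, p_value=p,
                              gene_pair=(p1.gene, p2.gene))


def read_profiles_tsv(path) -> dict[str, PresenceAbsenceProfile]:
    """Read presence/absence profiles from long-format TSV (taxon, gene, present)."""
    df = pd.read_csv(path, sep="\t")
    required = {"taxon", "gene", "present"}
    if not required.issubset(df.columns):
        raise InvalidParameterError(
            f"profile TSV needs columns {sorted(required)}, got {list(df.columns)}")
    out = {}
    for gene, grp in df.groupby("gene", sort=True):
        out[str(gene)] = PresenceAbsenceProfile(
            gene=str(gene),
            calls=dict(zip(grp["taxon"].astype(str), grp["present"].astype(int) > 0)))
    return out
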