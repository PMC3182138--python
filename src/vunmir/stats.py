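"""Digital expression analysis of mature miRNAs.

Counts are normalized to transcripts per ten million (TPTM) by each
library's total clean reads.  Differential expression between a drought
library and its control uses the Audic-Claverie conditional distribution

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y!) / (1 + N2/N1)^(x+y+1)

evaluated in log space, with the two-tailed p-value p = 2q (or 2(1-q) when
q > 0.5) from the accumulated probability q = sum_{y'<=y} p(y'|x), and
Bonferroni adjustment across the matures tested.  Drought-associated
miRNAs satisfy three criteria: adjusted p < 0.01 in at least one genotype,
TPTM >= 100 in at least one library, and |log2(drought/control)| > 1 in at
least one genotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import nbinom

from .preprocess import UniqueRead, map_mismatch
from .seqs import normalize

TPTM_SCALE = 1e7
# beyond this x+y the closed negative-binomial form replaces direct summation
_SUMMATION_LIMIT = 10_000

# library column conventions: (control, drought) per genotype
LIB_COLUMNS = ("IT_C", "IT_D", "CB_C", "CB_D")
GENOTYPE_PAIRS = {"IT93K503-1": ("IT_C", "IT_D"), "CB46": ("CB_C", "CB_D")}


def tptm(count, library_total) -> float:
    """Transcripts per ten million."""
    if np.any(np.asarray(library_total) <= 0):
        raise ValueError("library total must be positive")
    return count / library_total * TPTM_SCALE


def log2_ratio(a: float, b: float) -> float:
    """log2(a/b); NaN (printed as N/A) when either value is zero."""
    if a <= 0 or b <= 0:
        return float("nan")
    return float(np.log2(a / b))


def ac_log_pmf(y, x, n1: float, n2: float):
    """log p(y|x) of the Audic-Claverie conditional distribution."""
    y = np.asarray(y)
    if np.any(y < 0) or x < 0 or n1 <= 0 or n2 <= 0:
        raise ValueError("counts must be non-negative and totals positive")
    r = np.log(n2 / n1)
    return (
        y * r
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * np.log1p(n2 / n1)
    )


def ac_conditional_probability(y, x, n1: float, n2: float):
    """p(y|x): the probability of seeing y counts in a library of n2 clean
    reads given x counts in a library of n1 clean reads."""
    return np.exp(ac_log_pmf(y, x, n1, n2))


def _log_upper_tail(x: int, y: int, n1: float, n2: float) -> float:
    """log of sum_{y' > y} p(y'|x), accumulated directly in log space so the
    small tail never suffers the cancellation of computing 1 - q."""
    total = -np.inf
    start = y + 1
    while True:
        ys = np.arange(start, start + 2048)
        lp = ac_log_pmf(ys, x, n1, n2)
        total = np.logaddexp(total, logsumexp(lp))
        # stop once the trailing term is negligible against the accumulated
        # mass and the terms are decaying
        if lp[-1] < lp[0] and lp[-1] < total - 80.0:
            return float(total)
        start += 2048


def ac_two_tailed_pvalue(x: int, y: int, n1: float, n2: float) -> float:
    """Two-tailed Audic-Claverie p-value for (x, y) counts with library
    totals (n1, n2); p = 2q, or 2(1-q) when the accumulated probability q
    exceeds one half (evaluated as twice the upper tail, summed directly,
    to avoid cancellation), capped into (0, 1]."""
    if x + y <= _SUMMATION_LIMIT:
        q = float(np.exp(logsumexp(ac_log_pmf(np.arange(y + 1), x, n1, n2))))
        if q <= 0.5:
            p = 2.0 * q
        else:
            p = 2.0 * float(np.exp(_log_upper_tail(x, y, n1, n2)))
    else:
        # identical distribution: negative binomial, size x+1, prob n1/(n1+n2)
        prob = n1 / (n1 + n2)
        q = float(nbinom.cdf(y, x + 1, prob))
        p = 2.0 * q if q <= 0.5 else 2.0 * float(nbinom.sf(y, x + 1, prob))
    return float(min(max(p, 1e-320), 1.0))


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


def quantify_mature(
    reads: Sequence[UniqueRead],
    matures: Mapping[str, str],
    library_ids: Sequence[str],
    mode: str = "exact",
    precursors: Mapping[str, str] | None = None,
    mature_intervals: Mapping[str, tuple[int, int]] | None = None,
    margin: int = 2,
) -> pd.DataFrame:
    """Per-library raw counts for each mature miRNA.

    ``exact``: sum of counts of unique reads identical to the mature.
    ``one_mismatch_to_precursor``: additionally counts reads mapping to the
    precursor's mature interval (within ``margin`` nt) with <= 1
    substitution — the SNP re-check mode.
    """
    n_libs = len(library_ids)
    by_seq = {r.sequence: r.counts for r in reads}
    rows = {}
    for mid, mseq in matures.items():
        mseq = normalize(mseq)
        counts = np.array(by_seq.get(mseq, np.zeros(n_libs, dtype=np.int64)))
        rows[mid] = counts.astype(np.int64)
    if mode == "one_mismatch_to_precursor":
        # precursors and mature_intervals are keyed by the mature id
        if precursors is None or mature_intervals is None:
            raise ValueError("precursors and mature intervals required")
        hits = map_mismatch(reads, precursors, 1)
        mature_seqs = {normalize(s) for s in matures.values()}
        counted: set[tuple[str, str]] = set()
        for h in hits:
            mid = h.reference_id
            if mid not in rows or h.read in mature_seqs:
                continue
            lo, hi = mature_intervals[mid]
            if h.strand == "+" and h.start >= lo - margin and h.end <= hi + margin:
                if (h.read, mid) not in counted:
                    counted.add((h.read, mid))
                    rows[mid] = rows[mid] + by_seq[h.read]
    elif mode != "exact":
        raise ValueError(f"unknown mode: {mode}")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(library_ids))


def tptm_matrix(counts: pd.DataFrame, totals: Mapping[str, int]) -> pd.DataFrame:
    return counts / pd.Series(totals)[counts.columns] * TPTM_SCALE


@dataclass
class DifferentialResult:
    """Per-genotype Audic-Claverie tests plus classification flags."""

    table: pd.DataFrame  # one row per mature


def differential_tests(
    counts: pd.DataFrame,
    totals: Mapping[str, int],
    genotype_pairs: Mapping[str, tuple[str, str]] = GENOTYPE_PAIRS,
    m: int | None = None,
) -> pd.DataFrame:
    """Audic-Claverie two-tailed tests (drought vs control) per genotype with
    Bonferroni adjustment; the multiplier m defaults to the number of
    matures tested per comparison."""
    tm = tptm_matrix(counts, totals)
    out = pd.DataFrame(index=counts.index)
    m = m if m is not None else len(counts)
    for gname, (ctrl, drt) in genotype_pairs.items():
        p = np.array(
            [
                ac_two_tailed_pvalue(int(x), int(y), totals[ctrl], totals[drt])
                for x, y in zip(counts[ctrl], counts[drt])
            ]
        )
        out[f"x_{gname}"] = counts[ctrl]
        out[f"y_{gname}"] = counts[drt]
        out[f"log2fc_{gname}"] = [
            log2_ratio(a, b) for a, b in zip(tm[drt], tm[ctrl])
        ]
        out[f"p_{gname}"] = p
        out[f"p_adj_{gname}"] = bonferroni(p, m)
    return out


def two_fold_pattern(
    tptm_df: pd.DataFrame,
    genotype_pairs: Mapping[str, tuple[str, str]] = GENOTYPE_PAIRS,
) -> pd.Series:
    """Per mature: which genotypes changed at least two-fold under drought.

    A genotype is two-fold when |log2(drought/control TPTM)| >= 1; an N/A
    ratio (zero on either side) counts as not two-fold.  Patterns are
    'both', 'only_<genotype>' or 'neither'."""
    genotypes = list(genotype_pairs)
    flags = {}
    for g, (ctrl, drt) in genotype_pairs.items():
        lr = np.array([log2_ratio(a, b) for a, b in zip(tptm_df[drt], tptm_df[ctrl])])
        flags[g] = (~np.isnan(lr)) & (np.abs(lr) >= 1.0)
    def pattern(i):
        a, b = flags[genotypes[0]][i], flags[genotypes[1]][i]
        if a and b:
            return "both"
        if a:
            return f"only_{genotypes[0]}"
        if b:
            return f"only_{genotypes[1]}"
        return "neither"
    return pd.Series([pattern(i) for i in range(len(tptm_df))], index=tptm_df.index)


def classify_drought_associated(
    counts: pd.DataFrame,
    totals: Mapping[str, int],
    genotype_pairs: Mapping[str, tuple[str, str]] = GENOTYPE_PAIRS,
    p_threshold: float = 0.01,
    min_tptm: float = 100.0,
    min_abs_log2: float = 1.0,
    m: int | None = None,
) -> pd.DataFrame:
    """Drought-associated classification per unique mature miRNA.

    Associated iff (1) adjusted p < p_threshold in at least one genotype,
    (2) TPTM >= min_tptm in at least one of the four libraries, and
    (3) |log2(drought/control)| > min_abs_log2 in at least one genotype.
    Direction follows the significant genotype(s); records where the two
    genotypes' significant changes disagree are flagged discordant."""
    tests = differential_tests(counts, totals, genotype_pairs, m)
    tm = tptm_matrix(counts, totals)
    genotypes = list(genotype_pairs)

    sig = np.column_stack([tests[f"p_adj_{g}"] < p_threshold for g in genotypes])
    lfc = np.column_stack([tests[f"log2fc_{g}"] for g in genotypes])
    big = np.zeros(lfc.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        big[~np.isnan(lfc)] = np.abs(lfc[~np.isnan(lfc)]) > min_abs_log2
    delta = np.column_stack(
        [tm[d].to_numpy() - tm[c].to_numpy() for c, d in genotype_pairs.values()]
    )

    c1 = sig.any(axis=1)
    c2 = (tm.to_numpy() >= min_tptm).any(axis=1)
    c3 = big.any(axis=1)
    associated = c1 & c2 & c3

    directions = []
    discordant = []
    for i in range(len(tests)):
        signs = {int(np.sign(delta[i, g])) for g in range(len(genotypes)) if sig[i, g]}
        signs.discard(0)
        discordant.append(len(signs) > 1)
        if len(signs) == 1:
            directions.append("up" if signs.pop() > 0 else "down")
        else:
            directions.append("")
    out = tests.copy()
    out["tptm_max"] = tm.max(axis=1)
    out["associated"] = associated
    out["direction"] = directions
    out["discordant"] = discordant
    out["two_fold_pattern"] = two_fold_pattern(tm, genotype_pairs).to_numpy()
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame  # libraries x components
    loadings: pd.DataFrame  # miRNAs x components
    variance_fractions: np.ndarray
    retained: pd.Index


def pca_expression(
    tptm_df: pd.DataFrame, min_combined_tptm: float = 50.0, pseudocount: float = 1.0
) -> PCAResult:
    """PCA of log2 miRNA expression across the four libraries.

    MiRNAs with combined expression below ``min_combined_tptm`` are dropped;
    the matrix is log2(TPTM + pseudocount)-transformed with libraries as
    observations and miRNAs as variables, column-centered, and decomposed
    by SVD (eigendecomposition of the covariance)."""
    kept = tptm_df[tptm_df.sum(axis=1) >= min_combined_tptm]
    if len(kept) < 2:
        raise ValueError("fewer than 2 miRNAs pass the expression filter")
    X = np.log2(kept.to_numpy(dtype=float).T + pseudocount)  # libs x miRNAs
    X = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    nz = S > 1e-12 * max(S[0], 1.0)
    U, S, Vt = U[:, nz], S[nz], Vt[nz]
    fractions = S**2 / np.sum(S**2)
    comps = [f"PC{i + 1}" for i in range(S.size)]
    scores = pd.DataFrame(U * S, index=tptm_df.columns, columns=comps)
    loadings = pd.DataFrame(Vt.T, index=kept.index, columns=comps)
    return PCAResult(scores, loadings, fractions, kept.index)


def pc1_contributions(result: PCAResult) -> pd.DataFrame:
    """Ranked squared PC1 loadings with cumulative variance fractions —
    the basis for picking the miRNAs that dominate the first component."""
    sq = result.loadings["PC1"] ** 2
    ranked = sq.sort_values(ascending=False)
    return pd.DataFrame(
        {"squared_loading": ranked, "cumulative": ranked.cumsum() / ranked.sum()}
    )
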