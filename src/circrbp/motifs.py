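"""k-mer enrichment and PWM-based RBP motif attribution.

The analytical core: compare 6-mer occurrence rates between differentially
expressed and non-DE circRNA sequence sets (two-sided Fisher exact test per
k-mer, BH-adjusted), map the enriched k-mers onto RBP position probability
matrices (hypergeometric over-representation of PWM-matching k-mers within
the enriched set), profile normalized motif frequencies across the five
region classes, and intersect body- vs flank-significant RBPs to flag
putative dual-role proteins (sequestered by circRNAs *and* involved in
their biogenesis).

Counting is single-strand: input sequences are already transcript-oriented
and RBPs bind the RNA, not its reverse complement.  k-mer windows
containing N are excluded from both numerators and totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BASES, PWMRecord
from .regions import REGION_KINDS, RegionSet

_BASE_TO_INT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_TO_INT[ord(_b)] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """DNA string -> int8 array with A=0 C=1 G=2 T=3, N (or other) = -1."""
    return _BASE_TO_INT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        idx = idx * 4 + BASES.index(ch)
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def count_kmers(sequences: Iterable[str], k: int) -> tuple[np.ndarray, int]:
    """Sliding-window k-mer counts over a sequence set.

    Returns a length-4**k count vector and the total number of valid
    windows (windows containing N are skipped and not counted in the
    total).  Sequences shorter than k contribute nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 12:
        raise ValueError("k > 12 not supported (4^k table too large)")
    counts = np.zeros(4**k, dtype=np.int64)
    total = 0
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    any_short = False
    for seq in sequences:
        if len(seq) < k:
            any_short = True
            continue
        enc = encode_sequence(seq)
        windows = np.lib.stride_tricks.sliding_window_view(enc, k)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        idx = windows[valid].astype(np.int64) @ powers
        counts += np.bincount(idx, minlength=4**k)
        total += int(valid.sum())
    if total == 0 and any_short:
        warnings.warn("all sequences shorter than k; zero k-mer windows", stacklevel=2)
    return counts, total


# ---------------------------------------------------------------------------
# Fisher exact test (two-sided, hypergeometric enumeration)
# ---------------------------------------------------------------------------

from scipy.special import gammaln


def _lchoose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed one (with the
    conventional small relative slack on the float comparison).
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    # log C(col1, x) + log C(n-col1, row1-x) - log C(n, row1), via gammaln
    logpmf = (
        _lchoose(col1, support)
        + _lchoose(n - col1, row1 - support)
        - _lchoose(n, row1)
    )
    pmf = np.exp(logpmf)
    obs = pmf[a - lo]
    p = float(pmf[pmf <= obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def hypergeom_upper_tail(x: int, universe: int, n_marked: int, n_drawn: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(universe, n_marked, n_drawn)."""
    return float(stats.hypergeom.sf(x - 1, universe, n_marked, n_drawn))


# ---------------------------------------------------------------------------
# k-mer enrichment
# ---------------------------------------------------------------------------

def kmer_enrichment(
    fg_sequences: Sequence[str],
    bg_sequences: Sequence[str],
    k: int = 6,
    motif_fdr: float = 0.1,
    per_sequence: bool = False,
) -> pd.DataFrame:
    """Per-k-mer enrichment of a foreground sequence set over a background.

    Occurrence totals (or per-sequence presence when ``per_sequence``) feed
    a two-sided Fisher exact test per k-mer; BH adjustment runs over all
    k-mers observed in either set.  ``log2_enrichment`` is the pseudocount-
    adjusted (+0.5) log2 rate ratio; a k-mer is called enriched when its
    FDR is below ``motif_fdr`` and the rate ratio is positive.
    """
    fg_sequences = list(fg_sequences)
    bg_sequences = list(bg_sequences)
    if not fg_sequences or not bg_sequences:
        raise ValueError("both sequence sets must be non-empty")
    if fg_sequences is bg_sequences:
        warnings.warn("foreground and background are the same object (self-comparison)", stacklevel=2)

    if per_sequence:
        def presence(seqs):
            counts = np.zeros(4**k, dtype=np.int64)
            for s in seqs:
                c, _ = count_kmers([s], k)
                counts += (c > 0)
            return counts, len(seqs)
        count_fg, total_fg = presence(fg_sequences)
        count_bg, total_bg = presence(bg_sequences)
    else:
        count_fg, total_fg = count_kmers(fg_sequences, k)
        count_bg, total_bg = count_kmers(bg_sequences, k)
    if total_fg == 0 or total_bg == 0:
        raise ValueError("a sequence set produced zero k-mer windows")

    with np.errstate(divide="ignore"):
        log2_enr = np.log2(((count_fg + 0.5) / total_fg) / ((count_bg + 0.5) / total_bg))

    observed = (count_fg + count_bg) > 0
    pvals = np.ones(4**k)
    for idx in np.flatnonzero(observed):
        a = int(count_fg[idx])
        c = int(count_bg[idx])
        pvals[idx] = fisher_exact_two_sided(a, total_fg - a, c, total_bg - c)
    fdr = np.ones(4**k)
    if observed.any():
        fdr[observed] = multipletests(pvals[observed], method="fdr_bh")[1]

    kmers = [index_to_kmer(i, k) for i in range(4**k)]
    table = pd.DataFrame(
        {
            "kmer": kmers,
            "count_fg": count_fg,
            "count_bg": count_bg,
            "total_fg": total_fg,
            "total_bg": total_bg,
            "log2_enrichment": log2_enr,
            "pvalue": pvals,
            "fdr": fdr,
        }
    ).set_index("kmer", drop=False)
    table["enriched"] = (table["fdr"] < motif_fdr) & (table["log2_enrichment"] > 0)
    return table


# ---------------------------------------------------------------------------
# PWM scoring
# ---------------------------------------------------------------------------

_PSEUDO = 1e-3  # probability floor inside the log-odds


def _pwm_logodds(pwm: PWMRecord) -> np.ndarray:
    """Per-position log2(p/0.25) with probabilities floored at 1e-3."""
    return np.log2(np.maximum(pwm.matrix, _PSEUDO) / 0.25)


def score_kmer_pwm(kmer: str, pwm: PWMRecord, threshold: float = 0.8) -> tuple[float, bool]:
    """Best normalized log-odds alignment of a k-mer against a PWM.

    The shorter of (k-mer, PWM) slides over the longer; at each offset the
    score is the summed positional log2(p/0.25) (probabilities floored at
    1e-3), normalized by the maximum achievable score for that offset.  A
    degenerate alignment whose maximum achievable score is <= 0 (e.g. a
    uniform PWM) is scored 0 and never matches.
    """
    lo = _pwm_logodds(pwm)
    enc = encode_sequence(kmer)
    if (enc < 0).any():
        raise ValueError(f"k-mer {kmer!r} contains non-ACGT characters")
    k = len(enc)
    L = lo.shape[0]
    best = 0.0
    per_pos_max = lo.max(axis=1)
    if L >= k:
        offsets = range(L - k + 1)
        for off in offsets:
            maxs = per_pos_max[off : off + k].sum()
            if maxs <= 0:
                continue
            s = lo[np.arange(off, off + k), enc].sum()
            best = max(best, s / maxs)
    else:
        for off in range(k - L + 1):
            maxs = per_pos_max.sum()
            if maxs <= 0:
                continue
            s = lo[np.arange(L), enc[off : off + L]].sum()
            best = max(best, s / maxs)
    return float(best), bool(best >= threshold)


def pwm_matching_kmers(pwm: PWMRecord, k: int, threshold: float = 0.8) -> np.ndarray:
    """Boolean mask over all 4**k k-mers: does the k-mer match the PWM?

    Vectorized equivalent of :func:`score_kmer_pwm` applied to the full
    k-mer universe.
    """
    lo = _pwm_logodds(pwm)
    L = lo.shape[0]
    per_pos_max = lo.max(axis=1)
    n = 4**k
    # enumerate all k-mers as a (4^k, k) base matrix
    idx = np.arange(n)
    digits = np.empty((n, k), dtype=np.int64)
    for pos in range(k - 1, -1, -1):
        digits[:, pos] = idx % 4
        idx = idx // 4
    best = np.zeros(n)
    if L >= k:
        for off in range(L - k + 1):
            maxs = per_pos_max[off : off + k].sum()
            if maxs <= 0:
                continue
            scores = lo[np.arange(off, off + k)[None, :], digits].sum(axis=1)
            best = np.maximum(best, scores / maxs)
    else:
        maxs = per_pos_max.sum()
        if maxs > 0:
            for off in range(k - L + 1):
                scores = lo[np.arange(L)[None, :], digits[:, off : off + L]].sum(axis=1)
                best = np.maximum(best, scores / maxs)
    return best >= threshold


# ---------------------------------------------------------------------------
# motif enrichment from enriched k-mers
# ---------------------------------------------------------------------------

@dataclass
class MotifEnrichmentResult:
    rbp_name: str
    source: str
    n_matching_kmers: int
    n_enriched_matching: int
    pvalue: float
    fdr: float
    direction: str = ""
    region_kind: str = ""
    no_matching_kmers: bool = False


def motif_enrichment_from_kmers(
    enrichment_table: pd.DataFrame,
    pwm_library: Sequence[PWMRecord],
    fdr_threshold: float = 0.1,
    match_threshold: float = 0.8,
    direction: str = "",
    region_kind: str = "",
) -> pd.DataFrame:
    """Attribute enriched k-mers to RBP PWMs by hypergeometric over-representation.

    Universe = all 4^k k-mers; for each PWM, the test asks whether the
    enriched k-mer set contains more PWM-matching k-mers than expected by
    chance.  BH runs across the PWM library; significance at
    ``fdr_threshold``.
    """
    if not len(pwm_library):
        raise ValueError("empty PWM library")
    k = len(enrichment_table["kmer"].iloc[0])
    universe = 4**k
    enriched_mask = enrichment_table["enriched"].to_numpy()
    if len(enriched_mask) != universe:
        # table may be a subset; rebuild full-universe mask from kmer strings
        enriched_mask = np.zeros(universe, dtype=bool)
        for km in enrichment_table.loc[enrichment_table["enriched"], "kmer"]:
            enriched_mask[kmer_to_index(km)] = True
    n_enriched = int(enriched_mask.sum())

    rows = []
    for pwm in pwm_library:
        matching = pwm_matching_kmers(pwm, k, threshold=match_threshold)
        n_match = int(matching.sum())
        x = int((matching & enriched_mask).sum())
        if n_match == 0:
            p, flagged = 1.0, True
        else:
            p = hypergeom_upper_tail(x, universe, n_match, n_enriched)
            flagged = False
        rows.append(
            MotifEnrichmentResult(
                rbp_name=pwm.rbp_name,
                source=pwm.source,
                n_matching_kmers=n_match,
                n_enriched_matching=x,
                pvalue=p,
                fdr=np.nan,
                direction=direction,
                region_kind=region_kind,
                no_matching_kmers=flagged,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["fdr"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["fdr"] < fdr_threshold
    return df


def region_motif_enrichment(
    regions_by_kind: Mapping[str, Mapping[str, RegionSet]],
    de_status: Mapping[str, str],
    pwm_library: Sequence[PWMRecord],
    k: int = 6,
    motif_fdr: float = 0.1,
    region_classes: Mapping[str, Sequence[str]] | None = None,
) -> dict[tuple[str, str], dict]:
    """k-mer + PWM enrichment per (region class, DE direction).

    ``region_classes`` maps an analysis name to the region kinds pooled for
    it (default: body = [body], flank = [flank5, flank3]).  Foreground =
    sequences of circRNAs with the given DE status, background = non-DE
    (null) circRNAs.  Directions with zero DE circRNAs are skipped with a
    warning.
    """
    if region_classes is None:
        region_classes = {"body": ["body"], "flank": ["flank5", "flank3"]}
    by_status: dict[str, list[str]] = {"up": [], "down": [], "null": []}
    for circ_id, status in de_status.items():
        by_status.setdefault(status, []).append(circ_id)
    if not by_status["null"]:
        raise ValueError("no non-DE (null) circRNAs to use as background")

    results: dict[tuple[str, str], dict] = {}
    for cls_name, kinds in region_classes.items():
        def seqs_for(ids):
            out = []
            for kind in kinds:
                pool = regions_by_kind[kind]
                out.extend(pool[c].sequence for c in ids if c in pool)
            return out

        bg = seqs_for(by_status["null"])
        for direction in ("up", "down"):
            ids = by_status[direction]
            if not ids:
                warnings.warn(f"no {direction}-DE circRNAs; skipping {cls_name}/{direction}", stacklevel=2)
                continue
            fg = seqs_for(ids)
            table = kmer_enrichment(fg, bg, k=k, motif_fdr=motif_fdr)
            motifs = motif_enrichment_from_kmers(
                table, pwm_library, fdr_threshold=motif_fdr,
                direction=f"{direction}_set", region_kind=cls_name,
            )
            results[(cls_name, direction)] = {"kmer_table": table, "motif_results": motifs}
    return results


# ---------------------------------------------------------------------------
# region-resolved motif frequency profile
# ---------------------------------------------------------------------------

def scan_pwm_hits(sequences: Iterable[str], pwm: PWMRecord, threshold: float = 0.8) -> tuple[int, float]:
    """Count sliding-window PWM matches over sequences; returns (hits, kb scanned)."""
    lo = _pwm_logodds(pwm)
    L = lo.shape[0]
    maxs = lo.max(axis=1).sum()
    hits = 0
    total_nt = 0
    for seq in sequences:
        total_nt += len(seq)
        if len(seq) < L or maxs <= 0:
            continue
        enc = encode_sequence(seq)
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        valid = (windows >= 0).all(axis=1)
        if not valid.any():
            continue
        scores = lo[np.arange(L)[None, :], windows[valid]].sum(axis=1)
        hits += int(np.sum(scores / maxs >= threshold))
    return hits, total_nt / 1000.0


def motif_frequency_profile(
    rbp_pwms: Sequence[PWMRecord],
    regions_by_kind: Mapping[str, Mapping[str, RegionSet]],
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Normalized PWM hit frequency (matches per kb) per RBP x region kind."""
    rows = []
    for pwm in rbp_pwms:
        for kind in REGION_KINDS:
            pool = regions_by_kind.get(kind, {})
            if not pool:
                raise ValueError(f"empty region class {kind!r}")
            hits, kb = scan_pwm_hits((rs.sequence for rs in pool.values()), pwm, threshold)
            rows.append(
                {
                    "rbp_name": pwm.rbp_name,
                    "region_kind": kind,
                    "hits": hits,
                    "kb_scanned": kb,
                    "normalized_frequency": hits / kb if kb > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def dual_role_intersection(body_results: pd.DataFrame, flank_results: pd.DataFrame) -> dict:
    """RBPs significant in both body and flank analyses (putative dual role)."""
    body_set = set(body_results.loc[body_results["significant"], "rbp_name"])
    flank_set = set(flank_results.loc[flank_results["significant"], "rbp_name"])
    both = body_set & flank_set
    return {
        "both": sorted(both),
        "body_only": sorted(body_set - flank_set),
        "flank_only": sorted(flank_set - body_set),
        "n_both": len(both),
        "n_body_only": len(body_set - flank_set),
        "n_flank_only": len(flank_set - body_set),
    }
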