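"""Permutation-based empirical false-discovery rates and the candidate
shortlist.

The null distribution of the scan's tested p-value is obtained by
re-running the full scan on phenotype tables whose line labels have been
permuted as whole blocks: each line's complete record set (all doses, all
vials) is reassigned to another line id. Block permutation preserves the
within-line dose pairing and the dose main effect while breaking every
genotype-phenotype link, which keeps the null honest for the interaction
test. Null p-values are pooled across markers within each permutation
(panel-wide empirical FDR), so each marker receives one FDR number.

For observed p-values p_1..p_M and B permutation null sets,

    raw_fdr(p_i) = [ (1/B) * sum_b #{null p in perm b <= p_i} ]
                   / max(1, #{observed p <= p_i})

and the reported q is the running minimum of raw_fdr over all thresholds
at least as permissive (monotonization), capped at 1. The MAF filter is
applied once to the observed genotypes; it depends on genotypes only, so
it is invariant under phenotype permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import FEATURE_PRIORITY, FeatureIndex, MarkerId, PhenotypeTable, GenotypePanel
from .gxe_scan import ScanConfig, ScanResult, scan

__all__ = [
    "FdrConfig",
    "FdrResult",
    "permute_phenotypes",
    "null_tested_pvalues",
    "empirical_fdr",
    "monotonize_q",
    "run_fdr",
    "annotate_marker",
    "shortlist",
]


@dataclass(frozen=True)
class FdrConfig:
    """Permutation-FDR parameters.

    n_permutations
        Number of phenotype permutations B. 100 is a desk-scale default;
        FDR percentages quoted to 1% resolution want B >= 1,000.
    fdr_cutoff_percent
        Shortlist cutoff on q*100. 27 is the screen's validation cutoff;
        25 is the stricter preset some summaries use. Both are plain
        presets — pass either.
    permutation_unit
        Only "line" (whole-block) permutation is supported.
    """

    n_permutations: int = 100
    fdr_cutoff_percent: float = 27.0
    seed: int = 0
    permutation_unit: str = "line"
    keep_null: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.fdr_cutoff_percent <= 100.0:
            raise ValueError("fdr_cutoff_percent must be in (0, 100]")
        if self.permutation_unit != "line":
            raise ValueError("only line-block permutation is supported")


@dataclass(frozen=True)
class FdrResult:
    """Per-marker empirical FDR, aligned with the observed p vector.

    ``raw_fdr`` is the unmonotonized ratio; ``q`` the monotonized,
    capped-at-1 value; ``rank`` the 1..M position in the (p, chrom, pos)
    ordering (NaN p-values rank last). ``null_pvalues`` is retained only
    when requested.
    """

    pvalues: np.ndarray
    raw_fdr: np.ndarray
    q: np.ndarray
    rank: np.ndarray
    n_permutations: int
    null_pvalues: tuple[np.ndarray, ...] | None = None


def permute_phenotypes(phen: PhenotypeTable, rng: np.random.Generator) -> PhenotypeTable:
    """Reassign each line's full record block to another line id, uniformly
    at random. The multiset of (dose, n_total, n_smurf) records is
    conserved exactly; only the line labels move."""
    ids = sorted(set(phen.df["line_id"]))
    perm = rng.permutation(len(ids))
    mapping = {ids[i]: ids[perm[i]] for i in range(len(ids))}
    return phen.with_line_ids(mapping)


def null_tested_pvalues(
    panel: GenotypePanel,
    phen: PhenotypeTable,
    scan_config: ScanConfig,
    n_permutations: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Tested-term p-values from full re-scans of permuted phenotype tables,
    one array per permutation (identical ScanConfig throughout)."""
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # re-orientation chatter
        for _ in range(n_permutations):
            permuted = permute_phenotypes(phen, rng)
            out.append(scan(panel, permuted, scan_config).tested_pvalues.copy())
    return out


def monotonize_q(pvalues: np.ndarray, raw_fdr: np.ndarray) -> np.ndarray:
    """q_i = min over thresholds p_j >= p_i of raw_fdr(p_j), capped at 1.

    Computed as a running minimum from the least significant threshold
    downward, so q is non-decreasing in p.
    """
    p = np.asarray(pvalues, dtype=float)
    raw = np.asarray(raw_fdr, dtype=float)
    q = np.full_like(raw, np.nan)
    usable = np.flatnonzero(~np.isnan(p))
    order = usable[np.argsort(p[usable], kind="stable")]
    running = np.inf
    for i in order[::-1]:
        running = min(running, raw[i])
        q[i] = min(running, 1.0)
    return q


def empirical_fdr(
    observed_p: np.ndarray,
    null_p: Sequence[np.ndarray],
    keep_null: bool = False,
) -> FdrResult:
    """Empirical FDR of each observed p-value against pooled permutation
    nulls. Every null vector must have the same length as the observed one
    (one entry per retained marker). NaN entries (degenerate fits) are
    excluded from both numerator and denominator and get NaN q."""
    p = np.asarray(observed_p, dtype=float)
    M = p.size
    B = len(null_p)
    if B < 1:
        raise ValueError("at least one permutation null vector is required")
    for b, null in enumerate(null_p):
        if np.asarray(null).shape != (M,):
            raise ValueError(
                f"null p-vector {b} has shape {np.asarray(null).shape}, "
                f"expected ({M},) to match the observed marker set"
            )
    null_all = np.sort(np.concatenate([np.asarray(n, dtype=float) for n in null_p]))
    null_all = null_all[~np.isnan(null_all)]
    obs_sorted = np.sort(p[~np.isnan(p)])

    raw = np.full(M, np.nan)
    usable = ~np.isnan(p)
    mean_null_count = np.searchsorted(null_all, p[usable], side="right") / B
    obs_count = np.searchsorted(obs_sorted, p[usable], side="right")
    raw[usable] = mean_null_count / np.maximum(1, obs_count)

    q = monotonize_q(p, raw)

    rank = np.full(M, 0, dtype=int)
    order = np.argsort(np.where(np.isnan(p), np.inf, p), kind="stable")
    rank[order] = np.arange(1, M + 1)

    return FdrResult(
        pvalues=p,
        raw_fdr=raw,
        q=q,
        rank=rank,
        n_permutations=B,
        null_pvalues=tuple(np.asarray(n, dtype=float) for n in null_p) if keep_null else None,
    )


def run_fdr(
    panel: GenotypePanel,
    phen: PhenotypeTable,
    scan_config: ScanConfig | None = None,
    fdr_config: FdrConfig | None = None,
) -> tuple[ScanResult, FdrResult]:
    """Observed scan plus B permutation re-scans, seeded from the config."""
    scan_config = scan_config or ScanConfig()
    fdr_config = fdr_config or FdrConfig()
    observed = scan(panel, phen, scan_config)
    rng = np.random.default_rng(fdr_config.seed)
    nulls = null_tested_pvalues(panel, phen, scan_config, fdr_config.n_permutations, rng)
    fdr = empirical_fdr(observed.tested_pvalues, nulls, keep_null=fdr_config.keep_null)
    return observed, fdr


def annotate_marker(marker: MarkerId, features: FeatureIndex) -> tuple[str, str]:
    """Location class and gene of the innermost feature containing the
    marker; overlapping classes resolve as EXON > INTRON > NON_CODING.
    Positions inside no feature (or on chromosomes absent from the index,
    with a warning) are INTERGENIC."""
    if marker.chrom not in features.chroms:
        warnings.warn(f"chromosome {marker.chrom!r} absent from feature index")
        return "INTERGENIC", ""
    hits = features.query(marker.chrom, marker.pos)
    if not hits:
        return "INTERGENIC", ""
    best = min(hits, key=lambda f: (FEATURE_PRIORITY[f.feature_class], f.length))
    return best.feature_class, best.gene


def shortlist(
    scan_result: ScanResult,
    fdr: FdrResult,
    annotation: FeatureIndex | None = None,
    cutoff_percent: float = 27.0,
) -> pd.DataFrame:
    """Candidate table: markers with q*100 <= cutoff, ascending p, with
    gene/location columns filled from the annotation when given."""
    if len(scan_result.markers) != fdr.pvalues.size:
        raise ValueError("scan result and FDR result cover different marker sets")
    rows = []
    for i in scan_result.ranking():
        qpct = fdr.q[i] * 100.0
        if np.isnan(qpct) or qpct > cutoff_percent:
            continue
        marker = scan_result.markers[i]
        location, gene = ("", "")
        if annotation is not None:
            location, gene = annotate_marker(marker, annotation)
        rows.append(
            {
                "marker": str(marker),
                "gene": gene,
                "location": location,
                "p": float(fdr.pvalues[i]),
                "fdr_percent": float(qpct),
            }
        )
    return pd.DataFrame(rows, columns=["marker", "gene", "location", "p", "fdr_percent"])
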