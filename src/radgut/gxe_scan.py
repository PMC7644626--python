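"""Per-marker genotype x irradiation-dose association scan.

Each marker that survives a minor-allele-frequency filter (strictly greater
than ``maf_min``, default 0.25) is fit by ordinary least squares to

    phenotype = b0 + b1 * Genotype + b2 * Dose + b3 * Genotype * Dose

where the phenotype is the per-line Smurf proportion (vials pooled by
default), Genotype is the 0/1 minor-allele call of a homozygous inbred line
and Dose is the irradiation dose (0/1 indicator by default, raw Gy
optionally). Two-sided p-values for each coefficient come from the
Student-t distribution on n_obs - 4 degrees of freedom. The interaction
term b3 captures the irradiation-dependent portion of genetic influence on
the phenotype and is the tested term by default.

No kinship or structure correction and no covariates are applied; the model
is exactly the four-parameter linear model above, fit independently per
marker. ``scan`` evaluates all markers at once through closed-form normal
equations assembled with matrix products, so null-calibration and
permutation experiments with thousands of markers run in milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenotypePanel, MarkerId, PhenotypeTable

__all__ = [
    "ScanConfig",
    "MarkerFit",
    "ScanResult",
    "minor_allele_frequency",
    "filter_markers",
    "fit_marker_model",
    "scan",
    "TERM_INDEX",
]

TERM_INDEX = {"intercept": 0, "genotype": 1, "dose": 2, "interaction": 3}

_MIN_OBS = 5  # df = n_obs - 4 >= 1 for a finite p

# relative threshold below which the residual variance counts as exactly zero
_ZERO_RESID_RTOL = 1e-12


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    maf_min
        Markers are retained when their minor-allele frequency is strictly
        greater than this (default 0.25, i.e. the ">25% MAF" screen rule).
    dose_coding
        "binary" codes any positive dose as 1 (the screen has two dose
        levels, so this is the raw-Gy coding up to scale); "gray" uses Gy.
    response
        "proportion" regresses the raw Smurf proportion;
        "logit_proportion" uses log((s + 0.5) / (n - s + 0.5)) — the
        Haldane–Anscombe correction guards all-Smurf and no-Smurf records.
    tested_term
        Which coefficient's p-value the scan reports (default the
        genotype x dose interaction).
    min_lines_per_cell
        Markers with fewer phenotyped lines than this on either side of the
        allele split are flagged degenerate by :func:`scan`.
    pool_vials
        Pool vial records into one observation per line x dose (default);
        otherwise each vial is an observation.
    """

    maf_min: float = 0.25
    dose_coding: str = "binary"
    response: str = "proportion"
    tested_term: str = "interaction"
    min_lines_per_cell: int = 3
    pool_vials: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5), got {self.maf_min}")
        if self.dose_coding not in ("binary", "gray"):
            raise ValueError(f"unknown dose_coding {self.dose_coding!r}")
        if self.response not in ("proportion", "logit_proportion"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.tested_term not in TERM_INDEX:
            raise ValueError(f"unknown tested_term {self.tested_term!r}")
        if self.min_lines_per_cell < 1:
            raise ValueError("min_lines_per_cell must be >= 1")


@dataclass(frozen=True)
class MarkerFit:
    """OLS fit of one marker: coefficients (b0, b1, b2, b3), their standard
    errors, t statistics and two-sided p-values. ``degenerate`` marks fits
    with a rank-deficient design or zero residual variance (p undefined)."""

    marker: MarkerId | None
    n_obs: int
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    degenerate: bool = False
    n_lines: int = 0

    @property
    def beta_interaction(self) -> float:
        return float(self.params[TERM_INDEX["interaction"]])


@dataclass(frozen=True)
class ScanResult:
    """Fits for every marker passing the MAF filter, in panel order."""

    markers: tuple[MarkerId, ...]
    params: np.ndarray  # (M, 4)
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray  # (M, 4)
    n_obs: np.ndarray  # (M,)
    n_lines: np.ndarray  # (M,) distinct phenotyped lines with a call
    degenerate: np.ndarray  # (M,) bool
    tested_term: str
    config: ScanConfig
    n_reoriented: int = 0
    reoriented: np.ndarray | None = None  # (M,) bool; True where 0/1 were swapped

    def oriented_params(self) -> np.ndarray:
        """Coefficients expressed in the input file's allele coding: the
        genotype and interaction columns of re-oriented markers are
        sign-flipped back (their intercept/dose change too, but the file
        orientation of b1/b3 is what effect-recovery comparisons need)."""
        out = self.params.copy()
        if self.reoriented is not None and self.reoriented.any():
            out[self.reoriented, 1] *= -1.0
            out[self.reoriented, 3] *= -1.0
        return out

    @property
    def tested_pvalues(self) -> np.ndarray:
        return self.pvalues[:, TERM_INDEX[self.tested_term]]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def fit(self, i: int) -> MarkerFit:
        return MarkerFit(
            marker=self.markers[i],
            n_obs=int(self.n_obs[i]),
            params=self.params[i],
            bse=self.bse[i],
            tvalues=self.tvalues[i],
            pvalues=self.pvalues[i],
            degenerate=bool(self.degenerate[i]),
            n_lines=int(self.n_lines[i]),
        )

    def ranking(self) -> np.ndarray:
        """Indices sorted by (tested p, chrom, pos); degenerate fits (p
        undefined) are excluded."""
        p = self.tested_pvalues
        usable = np.flatnonzero(~np.isnan(p))
        keys = sorted(usable, key=lambda i: (p[i], self.markers[i].chrom, self.markers[i].pos))
        return np.asarray(keys, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        term = TERM_INDEX["interaction"]
        return pd.DataFrame(
            {
                "marker": [str(m) for m in self.markers],
                "chrom": [m.chrom for m in self.markers],
                "pos": [m.pos for m in self.markers],
                "class": [m.var_class for m in self.markers],
                "n_lines_used": self.n_lines,
                "beta_interaction": self.params[:, term],
                "se": self.bse[:, term],
                "t": self.tvalues[:, term],
                "p": self.pvalues[:, TERM_INDEX[self.tested_term]],
            }
        )


# ---------------------------------------------------------------------------
# MAF


def minor_allele_frequency(calls: Sequence[float] | np.ndarray) -> float:
    """Frequency of the rarer allele among non-missing 0/1 calls.

    Missing calls are excluded from the denominator; an all-missing vector
    raises. Always in [0, 0.5] and invariant to swapping the 0/1 labels.
    """
    arr = np.asarray(calls, dtype=float)
    valid = ~np.isnan(arr)
    if not valid.any():
        raise ValueError("minor allele frequency undefined: all calls missing")
    freq1 = float(arr[valid].mean())
    return min(freq1, 1.0 - freq1)


def _panel_mafs(panel: GenotypePanel) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        freq1 = np.nanmean(panel.calls, axis=1)
    return np.minimum(freq1, 1.0 - freq1)


def filter_markers(panel: GenotypePanel, maf_min: float = 0.25) -> GenotypePanel:
    """Retain exactly the markers with MAF strictly greater than ``maf_min``
    (so a marker at exactly the threshold is excluded), preserving order."""
    maf = _panel_mafs(panel)
    keep = np.zeros(panel.n_markers, dtype=bool)
    finite = ~np.isnan(maf)
    keep[finite] = maf[finite] > maf_min
    return panel.subset_markers(keep)


# ---------------------------------------------------------------------------
# response assembly


def _logit_ha(n_smurf: np.ndarray, n_total: np.ndarray) -> np.ndarray:
    return np.log((n_smurf + 0.5) / (n_total - n_smurf + 0.5))


def build_observations(phen: PhenotypeTable, config: ScanConfig) -> pd.DataFrame:
    """Turn the phenotype table into regression observations.

    Returns a frame with columns line_id, dose (coded), y. Vials are pooled
    per line x dose unless ``config.pool_vials`` is False.
    """
    df = phen.df
    if config.pool_vials:
        df = (
            df.groupby(["line_id", "dose_gy"], sort=False, as_index=False)[
                ["n_total", "n_smurf"]
            ].sum()
        )
    doses = np.sort(df["dose_gy"].unique())
    if len(doses) < 2:
        raise ValueError("at least two distinct dose levels are required for a scan")
    if config.dose_coding == "binary":
        dose = (df["dose_gy"].to_numpy() > 0).astype(float)
    else:
        dose = df["dose_gy"].to_numpy(dtype=float)
    n_total = df["n_total"].to_numpy(dtype=float)
    n_smurf = df["n_smurf"].to_numpy(dtype=float)
    if config.response == "proportion":
        y = n_smurf / n_total
    else:
        y = _logit_ha(n_smurf, n_total)
    return pd.DataFrame({"line_id": df["line_id"].to_numpy(), "dose": dose, "y": y})


# ---------------------------------------------------------------------------
# single-marker fit (explicit design matrix; the batched scan below uses
# normal equations and is cross-checked against this path in the tests)


def fit_marker_model(
    calls: Mapping[str, float] | pd.Series,
    phenotypes: PhenotypeTable,
    config: ScanConfig | None = None,
    marker: MarkerId | None = None,
) -> MarkerFit:
    """Fit the four-parameter interaction model for a single marker.

    ``calls`` maps line_id to the 0/1 call (NaN = missing); observations
    whose line has a missing call are dropped. Requires at least 5 usable
    observations (df >= 1). A rank-deficient design (e.g. a marker that is
    monomorphic after dropping) yields a degenerate fit with NaN
    coefficients; zero residual variance yields exact coefficients with the
    degenerate flag set and undefined p.
    """
    config = config or ScanConfig()
    if isinstance(calls, pd.Series):
        calls = calls.to_dict()
    obs = build_observations(phenotypes, config)
    g = obs["line_id"].map(lambda lid: calls.get(lid, np.nan)).to_numpy(dtype=float)
    keep = ~np.isnan(g)
    lines_used = obs["line_id"][keep].nunique()
    g, x, y = g[keep], obs["dose"].to_numpy()[keep], obs["y"].to_numpy()[keep]
    n = int(keep.sum())
    if n < _MIN_OBS:
        raise ValueError(
            f"insufficient data: {n} usable observations, need >= {_MIN_OBS}"
        )
    X = np.column_stack([np.ones(n), g, x, g * x])
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        nan4 = np.full(4, np.nan)
        return MarkerFit(
            marker, n, nan4, nan4.copy(), nan4.copy(), nan4.copy(), True, lines_used
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    df_resid = n - 4
    scale = max(1.0, float(y @ y))
    if ssr <= _ZERO_RESID_RTOL * scale:
        zero = np.zeros(4)
        nan4 = np.full(4, np.nan)
        return MarkerFit(marker, n, beta, zero, nan4, nan4.copy(), True, lines_used)
    sigma2 = ssr / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)
    bse = np.sqrt(np.diag(cov))
    tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return MarkerFit(marker, n, beta, bse, tvals, pvals, False, lines_used)


# ---------------------------------------------------------------------------
# batched scan


def _line_sufficient_stats(obs: pd.DataFrame, line_ids: Sequence[str]) -> dict[str, np.ndarray]:
    """Per-line sums over observations: count, Sx, Sxx, Sy, Sxy, Syy."""
    idx = {lid: i for i, lid in enumerate(line_ids)}
    L = len(line_ids)
    out = {k: np.zeros(L) for k in ("s0", "sx", "sxx", "sy", "sxy", "syy")}
    li = obs["line_id"].map(idx)
    if li.isna().any():
        # observations for lines absent from the panel are ignored
        obs = obs[~li.isna()]
        li = li[~li.isna()]
    li = li.to_numpy(dtype=int)
    x = obs["dose"].to_numpy()
    y = obs["y"].to_numpy()
    np.add.at(out["s0"], li, 1.0)
    np.add.at(out["sx"], li, x)
    np.add.at(out["sxx"], li, x * x)
    np.add.at(out["sy"], li, y)
    np.add.at(out["sxy"], li, x * y)
    np.add.at(out["syy"], li, y * y)
    return out


def scan(
    panel: GenotypePanel,
    phenotypes: PhenotypeTable,
    config: ScanConfig | None = None,
) -> ScanResult:
    """MAF-filter the panel and fit the interaction model at every retained
    marker.

    The calls file orients 1 = minor allele, but after line filtering the
    empirical frequency can disagree; markers whose call-1 frequency among
    phenotyped lines exceeds 50% are re-oriented (0 <-> 1) with a warning,
    which flips the sign of b1/b3 but leaves p-values unchanged.

    Deterministic given inputs and config. Raises when panel and phenotype
    line ids share fewer than 5 lines.
    """
    config = config or ScanConfig()
    panel_lines = set(panel.line_ids)
    phen_lines = set(phenotypes.line_ids)
    shared = panel_lines & phen_lines
    if len(shared) < _MIN_OBS:
        unmatched = sorted(phen_lines - panel_lines)
        raise ValueError(
            f"panel and phenotypes share only {len(shared)} lines (>= {_MIN_OBS} "
            f"required); phenotype lines missing from panel: {unmatched}"
        )

    filtered = filter_markers(panel, config.maf_min)
    M, L = filtered.n_markers, filtered.n_lines
    if M == 0:
        empty = np.empty((0, 4))
        return ScanResult(
            markers=(),
            params=empty,
            bse=empty.copy(),
            tvalues=empty.copy(),
            pvalues=empty.copy(),
            n_obs=np.empty(0, dtype=int),
            n_lines=np.empty(0, dtype=int),
            degenerate=np.empty(0, dtype=bool),
            tested_term=config.tested_term,
            config=config,
            reoriented=np.empty(0, dtype=bool),
        )

    obs = build_observations(phenotypes, config)
    ss = _line_sufficient_stats(obs, filtered.line_ids)
    has_phen = ss["s0"] > 0

    W = (~np.isnan(filtered.calls)).astype(float)
    G = np.nan_to_num(filtered.calls, nan=0.0) * W

    # re-orient markers whose call-1 frequency among phenotyped lines > 50%
    used = W * has_phen
    with np.errstate(invalid="ignore", divide="ignore"):
        freq1 = (G * has_phen).sum(axis=1) / used.sum(axis=1)
    flip = freq1 > 0.5
    n_reoriented = int(flip.sum())
    if n_reoriented:
        warnings.warn(
            f"{n_reoriented} marker(s) had call-1 frequency > 50% among phenotyped "
            "lines and were re-oriented so that 1 = minor allele"
        )
        G[flip] = W[flip] - G[flip]

    # per-marker sums over usable observations; calls are 0/1 so g**2 == g
    n = W @ ss["s0"]
    Sg = G @ ss["s0"]
    Sx = W @ ss["sx"]
    Sgx = G @ ss["sx"]
    Sxx = W @ ss["sxx"]
    Sgxx = G @ ss["sxx"]
    Sy = W @ ss["sy"]
    Sgy = G @ ss["sy"]
    Sxy = W @ ss["sxy"]
    Sgxy = G @ ss["sxy"]
    Syy = W @ ss["syy"]

    XtX = np.empty((M, 4, 4))
    XtX[:, 0, 0] = n
    XtX[:, 0, 1] = XtX[:, 1, 0] = Sg
    XtX[:, 0, 2] = XtX[:, 2, 0] = Sx
    XtX[:, 0, 3] = XtX[:, 3, 0] = Sgx
    XtX[:, 1, 1] = Sg
    XtX[:, 1, 2] = XtX[:, 2, 1] = Sgx
    XtX[:, 1, 3] = XtX[:, 3, 1] = Sgx
    XtX[:, 2, 2] = Sxx
    XtX[:, 2, 3] = XtX[:, 3, 2] = Sgxx
    XtX[:, 3, 3] = Sgxx
    Xty = np.stack([Sy, Sgy, Sxy, Sgxy], axis=1)

    carriers = (G * has_phen).astype(bool).sum(axis=1)
    noncarriers = (used.astype(bool) & ~(G * has_phen).astype(bool)).sum(axis=1)
    thin_cells = (carriers < config.min_lines_per_cell) | (
        noncarriers < config.min_lines_per_cell
    )
    rank = np.linalg.matrix_rank(XtX)
    too_few = n < _MIN_OBS
    rank_bad = (rank < 4) | too_few | thin_cells

    params = np.full((M, 4), np.nan)
    bse = np.full((M, 4), np.nan)
    tvalues = np.full((M, 4), np.nan)
    pvalues = np.full((M, 4), np.nan)
    degenerate = rank_bad.copy()

    ok = ~rank_bad
    if ok.any():
        beta = np.linalg.solve(XtX[ok], Xty[ok][..., None])[..., 0]
        ssr = Syy[ok] - np.einsum("ij,ij->i", beta, Xty[ok])
        ssr = np.maximum(ssr, 0.0)
        df_resid = n[ok] - 4
        scale = np.maximum(1.0, Syy[ok])
        zero_resid = ssr <= _ZERO_RESID_RTOL * scale
        sigma2 = ssr / df_resid
        inv = np.linalg.inv(XtX[ok])
        diag = np.einsum("ijj->ij", inv)
        se = np.sqrt(sigma2[:, None] * diag)
        params[ok] = beta
        with np.errstate(invalid="ignore", divide="ignore"):
            tv = beta / se
            pv = 2.0 * stats.t.sf(np.abs(tv), df_resid[:, None])
        tv[zero_resid] = np.nan
        pv[zero_resid] = np.nan
        se[zero_resid] = 0.0
        bse[ok] = se
        tvalues[ok] = tv
        pvalues[ok] = pv
        ok_idx = np.flatnonzero(ok)
        degenerate[ok_idx[zero_resid]] = True

    return ScanResult(
        markers=filtered.markers,
        params=params,
        bse=bse,
        tvalues=tvalues,
        pvalues=pvalues,
        n_obs=n.astype(int),
        n_lines=(carriers + noncarriers).astype(int),
        degenerate=degenerate,
        reoriented=np.asarray(flip, dtype=bool),
        tested_term=config.tested_term,
        config=config,
        n_reoriented=n_reoriented,
    )
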