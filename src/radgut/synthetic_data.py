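"""Synthetic DGRP-like panels, Smurf phenotypes, survival tables and 3'UTR
sets with planted ground truth.

The generator emulates the screen's study design: a panel of ~156 fully
inbred (homozygous) lines, each phenotyped with ~100 flies split over vials
in paired 0 Gy / 100 Gy conditions. Genotypes are independent across
markers and lines (no linkage disequilibrium, inversions or population
structure — the downstream model fits none of these either). Phenotypes
follow the same linear structure the scan fits:

    latent(line, dose) = baseline_p + dose_effect * [dose > 0]
                         + sum_causal (b_G * g + b_GxD * g * [dose > 0])
                         + line_effect,     line_effect ~ N(0, line_sd^2)

mapped to a probability (identity with clamping on the proportion scale,
inverse-logit on the logit scale), and observed Smurf counts are Binomial
per vial. Planted causal markers and realized latent probabilities are
returned as :class:`SimTruth` so recovery tests have exact ground truth.

All randomness flows from a single seed; per-stage sub-streams are derived
deterministically so, e.g., regenerating phenotypes does not disturb the
panel draw.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenotypePanel, MarkerId, PhenotypeTable, SurvivalTable, UtrSet
from .mbe_scan import DEFAULT_MBE_PATTERN, MbeConfig, find_mbe_sites

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_panel",
    "simulate_phenotypes",
    "simulate_dataset",
    "simulate_survival",
    "simulate_utrs",
]

_CHROM_ARMS = ("2L", "2R", "3L", "3R", "X")

# fixed stage offsets for deriving independent sub-streams from one seed
_STAGE = {"panel": 0, "phenotypes": 1, "survival": 2, "utrs": 3}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STAGE[stage])))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic screen.

    Defaults mirror the screen's conditions: 156 lines, ~100 flies per line
    and condition (4 vials of 25), doses 0 and 100 Gy. Where the design
    gives no number, the defaults are a documented choice: control Smurf
    incidence baseline_p = 0.05 with dose_effect = +0.15 (irradiated lines
    average ~20% Smurfs), and a Gaussian per-line random effect with
    line_sd = 0.05 on the proportion scale, loosely calibrated to the
    between-line spread the screen observed.

    causal_markers is a sequence of (marker_index, b_G, b_GxD) triples
    planting a genotype main effect and a genotype x dose interaction at
    the given marker, on the modeling scale selected by ``scale``.
    """

    n_lines: int = 156
    n_markers: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_flies_per_line: int = 100
    n_vials: int = 4
    doses: tuple[float, ...] = (0.0, 100.0)
    baseline_p: float = 0.05
    dose_effect: float = 0.15
    causal_markers: tuple[tuple[int, float, float], ...] = ()
    causal_maf_range: tuple[float, float] | None = None
    line_sd: float = 0.05
    missing_rate: float = 0.0
    scale: str = "proportion"
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.maf_range
        if low > high:
            raise ValueError(f"degenerate maf_range: low {low} > high {high}")
        if not (0.0 < low <= 0.5 and 0.0 < high <= 0.5):
            raise ValueError("maf_range bounds must lie in (0, 0.5]")
        if not 0.0 < self.baseline_p < 1.0:
            raise ValueError("baseline_p must be in (0, 1)")
        if self.n_lines < 2 or self.n_markers < 1:
            raise ValueError("need at least 2 lines and 1 marker")
        if self.n_flies_per_line < 1:
            raise ValueError("n_flies_per_line must be >= 1")
        if self.n_vials < 1 or self.n_flies_per_line % self.n_vials != 0:
            raise ValueError("n_vials must divide n_flies_per_line")
        if len(self.doses) < 2 or len(set(self.doses)) != len(self.doses):
            raise ValueError("doses must be >= 2 distinct values")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be non-negative")
        if self.scale not in ("proportion", "logit"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for idx, _, _ in self.causal_markers:
            if not 0 <= idx < self.n_markers:
                raise ValueError(f"causal marker index {idx} out of range")
        if self.causal_maf_range is not None:
            lo, hi = self.causal_maf_range
            if lo > hi or not (0.0 < lo <= 0.5 and 0.0 < hi <= 0.5):
                raise ValueError("causal_maf_range bounds must lie in (0, 0.5] with low <= high")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth for one simulated dataset."""

    causal: tuple[tuple[MarkerId, float, float], ...]
    latent: pd.DataFrame | None = None  # line_id, dose_gy, probability
    n_clamped: int = 0


def simulate_panel(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Draw a marker-by-line panel of homozygous 0/1 calls.

    Each marker's minor-allele frequency is uniform over ``maf_range`` and
    each line's call is an independent Bernoulli draw (inbred lines carry a
    single call). Marker ids are SNPs at increasing positions on randomly
    assigned chromosome arms. Bit-reproducible under a fixed seed.
    """
    rng = _stage_rng(config.seed, "panel")
    M, L = config.n_markers, config.n_lines
    low, high = config.maf_range
    maf = rng.uniform(low, high, size=M)
    if config.causal_maf_range is not None and config.causal_markers:
        clo, chi = config.causal_maf_range
        idx = [i for i, _, _ in config.causal_markers]
        maf[idx] = rng.uniform(clo, chi, size=len(idx))
    calls = (rng.random((M, L)) < maf[:, None]).astype(float)
    if config.missing_rate > 0:
        calls[rng.random((M, L)) < config.missing_rate] = np.nan
    arms = rng.choice(len(_CHROM_ARMS), size=M)
    offsets = rng.integers(100, 5000, size=M)
    pos_by_arm = {a: 0 for a in range(len(_CHROM_ARMS))}
    markers = []
    for i in range(M):
        pos_by_arm[arms[i]] += int(offsets[i])
        markers.append(MarkerId(_CHROM_ARMS[arms[i]], pos_by_arm[arms[i]], "SNP"))
    line_ids = tuple(f"line_{i + 1:03d}" for i in range(L))
    panel = GenotypePanel(line_ids=line_ids, markers=tuple(markers), calls=calls)
    causal = tuple(
        (markers[idx], float(b_g), float(b_gxd)) for idx, b_g, b_gxd in config.causal_markers
    )
    return panel, SimTruth(causal=causal)


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_phenotypes(
    panel: GenotypePanel,
    config: SimConfig,
    truth: SimTruth | None = None,
) -> tuple[PhenotypeTable, SimTruth]:
    """Draw Smurf counts for every line x dose x vial.

    Line effects are Gaussian on the modeling scale and shared across doses
    within a line. On the proportion scale, latent values outside [0, 1]
    are clamped and counted (the count is reported in the returned truth);
    on the logit scale no clamping is needed. Returns the updated
    :class:`SimTruth` carrying realized latent probabilities.
    """
    if config.n_flies_per_line < 1:
        raise ValueError("n_flies_per_line must be >= 1")
    rng = _stage_rng(config.seed, "phenotypes")
    L = panel.n_lines
    if config.scale == "logit":
        p0 = config.baseline_p
        intercept = float(np.log(p0 / (1.0 - p0)))
    else:
        intercept = config.baseline_p

    line_effect = rng.normal(0.0, config.line_sd, size=L) if config.line_sd > 0 else np.zeros(L)

    causal = truth.causal if truth is not None else ()
    if truth is None and config.causal_markers:
        marker_index = {m: i for i, m in enumerate(panel.markers)}
        causal = tuple(
            (panel.markers[idx], float(b_g), float(b_gxd))
            for idx, b_g, b_gxd in config.causal_markers
        )
    marker_pos = {m: i for i, m in enumerate(panel.markers)}

    genetic_main = np.zeros(L)
    genetic_gxd = np.zeros(L)
    for marker, b_g, b_gxd in causal:
        g = np.nan_to_num(panel.calls[marker_pos[marker]], nan=0.0)
        genetic_main += b_g * g
        genetic_gxd += b_gxd * g

    flies_per_vial = config.n_flies_per_line // config.n_vials
    records = []
    latent_rows = []
    n_clamped = 0
    for dose in config.doses:
        irradiated = 1.0 if dose > 0 else 0.0
        latent = (
            intercept
            + config.dose_effect * irradiated
            + genetic_main
            + genetic_gxd * irradiated
            + line_effect
        )
        if config.scale == "logit":
            prob = _inv_logit(latent)
        else:
            clipped = np.clip(latent, 0.0, 1.0)
            n_clamped += int((clipped != latent).sum())
            prob = clipped
        smurfs = rng.binomial(flies_per_vial, prob[:, None], size=(L, config.n_vials))
        for li, lid in enumerate(panel.line_ids):
            latent_rows.append({"line_id": lid, "dose_gy": dose, "probability": prob[li]})
            for v in range(config.n_vials):
                records.append(
                    {
                        "line_id": lid,
                        "dose_gy": dose,
                        "vial_id": f"v{v + 1}",
                        "n_total": flies_per_vial,
                        "n_smurf": int(smurfs[li, v]),
                    }
                )
    phen = PhenotypeTable(pd.DataFrame.from_records(records))
    new_truth = SimTruth(
        causal=causal,
        latent=pd.DataFrame.from_records(latent_rows),
        n_clamped=n_clamped,
    )
    return phen, new_truth


def simulate_dataset(config: SimConfig) -> tuple[GenotypePanel, PhenotypeTable, SimTruth]:
    """Panel + phenotypes + truth in one call."""
    panel, truth = simulate_panel(config)
    phen, truth = simulate_phenotypes(panel, config, truth)
    return panel, phen, truth


def simulate_survival(
    n_per_group: Mapping[str, int],
    hazard: Mapping[str, float | tuple[float, float]],
    censor_day: float | None = None,
    law: str = "exponential",
    seed: int = 0,
) -> SurvivalTable:
    """Draw lifespans per group from an exponential or Gompertz law.

    ``hazard`` maps group to the exponential rate (deaths/day) or, for the
    Gompertz law, to a (shape a, rate b) pair with survival
    S(t) = exp(-(b/a)(e^{at} - 1)). Subjects alive at ``censor_day`` are
    right-censored there.
    """
    if law not in ("exponential", "gompertz"):
        raise ValueError(f"unknown survival law {law!r}")
    rng = _stage_rng(seed, "survival")
    rows = []
    for group, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"group {group!r} has non-positive size")
        params = hazard[group]
        if law == "exponential":
            times = rng.exponential(1.0 / float(params), size=n)
        else:
            a, b = params
            u = rng.random(n)
            times = np.log1p(-a * np.log(u) / b) / a
        times = np.maximum(times, 1e-9)
        for t in times:
            if censor_day is not None and t > censor_day:
                rows.append({"group": group, "time": float(censor_day), "event": 0})
            else:
                rows.append({"group": group, "time": float(t), "event": 1})
    return SurvivalTable(pd.DataFrame.from_records(rows))


def _sample_motif(rng: np.random.Generator, pattern: str) -> str:
    # concrete realization of the consensus (G/A)U(1-3)AGU
    if pattern != DEFAULT_MBE_PATTERN:
        raise ValueError(
            "motif planting supports only the default consensus pattern; "
            "plant custom motifs by passing explicit sequences"
        )
    head = "G" if rng.random() < 0.5 else "A"
    return head + "U" * int(rng.integers(1, 4)) + "AGU"


def simulate_utrs(
    n_genes: int,
    length: int,
    planted_counts: Sequence[int],
    seed: int = 0,
    pattern: str = DEFAULT_MBE_PATTERN,
    max_attempts: int = 2000,
) -> tuple[UtrSet, dict[str, int]]:
    """Random RNA 3'UTRs with an exact planted number of MBE sites each.

    Backgrounds are uniform over {A,C,G,U}; motif realizations are inserted
    at non-overlapping positions and the whole sequence is rejected and
    redrawn whenever the scan count differs from the target (accidental
    matches, including across insertion junctions, are thereby excluded).
    The returned dict maps gene name to its exact truth count.
    """
    if len(planted_counts) != n_genes:
        raise ValueError("planted_counts must have one entry per gene")
    rng = _stage_rng(seed, "utrs")
    config = MbeConfig(pattern=pattern)
    alphabet = np.array(list("ACGU"))
    sequences: dict[str, str] = {}
    truth: dict[str, int] = {}
    for gi in range(n_genes):
        target = int(planted_counts[gi])
        if target < 0:
            raise ValueError("planted counts must be non-negative")
        max_motif_len = 7  # longest consensus realization
        if target * max_motif_len > length:
            raise ValueError(
                f"cannot fit {target} motifs of up to {max_motif_len} nt in {length} nt"
            )
        name = f"gene_{gi + 1:03d}"
        for _ in range(max_attempts):
            seq = list(rng.choice(alphabet, size=length))
            motifs = [_sample_motif(rng, pattern) for _ in range(target)]
            total = sum(len(m) for m in motifs)
            # choose non-overlapping insertion slots by spacing sorted gaps
            slack = length - total
            gaps = np.sort(rng.integers(0, slack + 1, size=target)) if target else []
            pos = 0
            ok = True
            starts = []
            for k, m in enumerate(motifs):
                start = int(gaps[k]) + sum(len(mm) for mm in motifs[:k])
                if start < pos:
                    ok = False
                    break
                starts.append(start)
                pos = start + len(m)
            if not ok:
                continue
            for start, m in zip(starts, motifs):
                seq[start : start + len(m)] = list(m)
            candidate = "".join(seq)
            if len(find_mbe_sites(candidate, config)) == target:
                sequences[name] = candidate
                truth[name] = target
                break
        else:
            raise RuntimeError(
                f"could not realize exactly {target} motif(s) in {length} nt "
                f"after {max_attempts} attempts"
            )
    return UtrSet(sequences), truth
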