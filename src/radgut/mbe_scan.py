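"""Musashi-Binding-Element (MBE) scanning of 3'UTR sequences.

Musashi-family RNA-binding proteins repress translation of targets whose
3'UTRs carry MBE motifs. The scanner matches the literature consensus
(G/A)U(1-3)AGU — expressed as the regular expression ``[GA]U{1,3}AGU`` on
the RNA alphabet — against sense-strand UTR sequences and shortlists genes
with at least ``min_sites`` matches (default 4). DNA input is normalized
T -> U before matching; N never matches; the reverse complement is never
scanned implicitly (3'UTRs are sense-strand by contract).

The pattern is fully configurable, and an optional position-weight-matrix
mode (log-odds against a 0-order background, user-supplied matrix and
threshold) is available for users who have a scoring model; web-service
PSSM scores are not reproduced here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import UtrSet

__all__ = [
    "DEFAULT_MBE_PATTERN",
    "MbeConfig",
    "MbeReport",
    "normalize_rna",
    "find_mbe_sites",
    "shortlist_genes",
    "scan_pwm",
    "write_bed",
]

DEFAULT_MBE_PATTERN = "[GA]U{1,3}AGU"

_RNA_ALPHABET = frozenset("ACGUN")


@dataclass(frozen=True)
class MbeConfig:
    """Motif, shortlist threshold and overlap policy.

    Under ``non_overlapping_greedy`` (default) the scan resumes past each
    match, so reported sites are pairwise disjoint — "4 repeats" means four
    distinct elements. ``all_overlapping`` reports one (longest) match per
    start position instead.
    """

    pattern: str = DEFAULT_MBE_PATTERN
    min_sites: int = 4
    overlap_policy: str = "non_overlapping_greedy"

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise ValueError(f"invalid motif pattern {self.pattern!r}: {exc}") from None
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if self.overlap_policy not in ("non_overlapping_greedy", "all_overlapping"):
            raise ValueError(f"unknown overlap_policy {self.overlap_policy!r}")


@dataclass(frozen=True)
class MbeReport:
    """Per-gene site intervals (1-based, closed), counts and shortlist flags."""

    sites: dict[str, tuple[tuple[int, int], ...]]
    min_sites: int

    @property
    def counts(self) -> dict[str, int]:
        return {name: len(ivals) for name, ivals in self.sites.items()}

    @property
    def shortlisted(self) -> tuple[str, ...]:
        return tuple(n for n, ivals in self.sites.items() if len(ivals) >= self.min_sites)

    def is_shortlisted(self, name: str) -> bool:
        return len(self.sites[name]) >= self.min_sites

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.sites),
                "n_sites": [len(v) for v in self.sites.values()],
                "shortlisted": [len(v) >= self.min_sites for v in self.sites.values()],
            }
        )


def normalize_rna(seq: str) -> str:
    """Uppercase and convert T -> U; reject characters outside {A,C,G,T,U,N},
    naming the (1-based) offset of the first offender."""
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in _RNA_ALPHABET and ch != "T":
            raise ValueError(f"invalid character {ch!r} at position {i + 1}")
    return up.replace("T", "U")


def find_mbe_sites(
    seq: str, config: MbeConfig | None = None
) -> list[tuple[int, int]]:
    """MBE site intervals in one UTR, 1-based closed, ascending.

    The scan is left-to-right; under the greedy non-overlap policy it
    resumes immediately past each match.
    """
    config = config or MbeConfig()
    rna = normalize_rna(seq)
    rx = re.compile(config.pattern)
    if config.overlap_policy == "non_overlapping_greedy":
        return [(m.start() + 1, m.end()) for m in rx.finditer(rna)]
    sites = []
    for start in range(len(rna)):
        m = rx.match(rna, start)
        if m and m.end() > m.start():
            sites.append((start + 1, m.end()))
    return sites


def shortlist_genes(utrs: UtrSet, config: MbeConfig | None = None) -> MbeReport:
    """Scan every UTR and flag genes with >= ``min_sites`` MBE sites."""
    config = config or MbeConfig()
    if len(utrs) == 0:
        raise ValueError("empty UTR set")
    sites = {name: tuple(find_mbe_sites(seq, config)) for name, seq in utrs}
    return MbeReport(sites=sites, min_sites=config.min_sites)


def scan_pwm(
    seq: str,
    pwm: Mapping[str, Sequence[float]] | pd.DataFrame,
    threshold: float,
    background: Mapping[str, float] | None = None,
) -> list[tuple[int, int]]:
    """Log-odds PWM scan (optional scoring mode).

    ``pwm`` maps each base A/C/G/U to per-position probabilities; scores are
    sum_i log2(pwm[base_i][i] / background[base_i]) over each window, and
    windows scoring >= ``threshold`` are reported as 1-based closed
    intervals. Windows containing N are skipped.
    """
    if isinstance(pwm, pd.DataFrame):
        pwm = {b: pwm.loc[b].tolist() for b in pwm.index}
    background = background or {b: 0.25 for b in "ACGU"}
    width = len(next(iter(pwm.values())))
    if any(len(v) != width for v in pwm.values()):
        raise ValueError("ragged PWM columns")
    rna = normalize_rna(seq)
    out = []
    for start in range(len(rna) - width + 1):
        window = rna[start : start + width]
        if "N" in window:
            continue
        score = 0.0
        for i, base in enumerate(window):
            p = pwm[base][i]
            if p <= 0:
                score = -np.inf
                break
            score += np.log2(p / background[base])
        if score >= threshold:
            out.append((start + 1, start + width))
    return out


def write_bed(report: MbeReport, path: str | Path) -> None:
    """Export sites as BED (0-based, half-open)."""
    with open(path, "w") as handle:
        for name, intervals in report.sites.items():
            for start, end in intervals:
                handle.write(f"{name}\t{start - 1}\t{end}\tMBE\n")
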