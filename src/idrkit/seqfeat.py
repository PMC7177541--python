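"""Residue-level and windowed sequence descriptors for disordered regions.

This module provides the scanning primitives used both to characterize a
single IDR construct (homopolymer runs, hydropathy profile, formal net
charge, charge-hydropathy classification, low-complexity entropy profile,
self-association motif scan) and to power the proteome-wide polyalanine
census.  All coordinates are 1-based, inclusive, in full-protein numbering
via :attr:`ProteinRecord.numbering_offset`.

Conventions
-----------
* Ambiguous letters (X/U/B/Z) break homopolymer runs and are excluded from
  charge, hydropathy, composition and entropy statistics.
* Windowed profiles report a missing value (NaN) at positions whose full
  window does not fit; windows are never shrunk at the edges.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import kyte_doolittle_values
from .records import AMBIGUOUS, CANONICAL, ProteinRecord, SequenceError

__all__ = [
    "ResidueScale", "HomopolymerRun", "MotifHit", "ChargeHydropathyPoint",
    "ChargeConvention", "BoundaryLine", "MotifConfig",
    "kyte_doolittle", "find_homopolymer_runs", "max_run_length",
    "hydropathy_profile", "formal_net_charge", "charge_hydropathy_point",
    "scan_motifs", "complexity_profile", "composition_fraction",
    "MOTIF_CLASSES",
]


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue numeric scale (e.g. hydropathy units).

    All twenty canonical residues must be present with finite values.
    """

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = sorted(set(CANONICAL) - set(self.values))
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {missing}")
        extra = sorted(set(self.values) - set(CANONICAL))
        if extra:
            raise ValueError(f"scale {self.name!r} has non-canonical keys: {extra}")
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has non-finite values")
        object.__setattr__(self, "values", dict(self.values))

    def scaled(self) -> "ResidueScale":
        """Min-max rescaling of the twenty values onto [0, 1]."""
        lo = min(self.values.values())
        hi = max(self.values.values())
        if hi == lo:
            raise ValueError("degenerate scale: all residues share one value")
        return ResidueScale(
            name=f"{self.name}_scaled01",
            values={k: (v - lo) / (hi - lo) for k, v in self.values.items()},
        )


def kyte_doolittle() -> ResidueScale:
    """The Kyte-Doolittle hydropathy scale as a :class:`ResidueScale`."""
    return ResidueScale("kyte_doolittle", kyte_doolittle_values())


@dataclass(frozen=True)
class ChargeConvention:
    """Which residues carry formal charge.

    The default treats Lys/Arg as +1, Asp/Glu as -1, histidine as neutral
    and ignores the termini, which is the usual convention for describing a
    construct by residue counts.  Set ``histidine_positive=True`` for the
    fully-protonated-His variant relevant at acidic pH.
    """

    histidine_positive: bool = False

    @property
    def positive(self) -> str:
        return "KRH" if self.histidine_positive else "KR"

    @property
    def negative(self) -> str:
        return "DE"


@dataclass(frozen=True)
class BoundaryLine:
    """Linear separator of the charge-hydropathy (Uversky) plane.

    A point with mean absolute net charge per residue ``R`` and mean
    min-max-scaled hydropathy ``H`` classifies as ``disordered_like`` when
    ``R >= slope * H + intercept`` (points exactly on the line count as
    disordered; natively unfolded proteins lie on the high-charge /
    low-hydropathy side).  The defaults are the standard empirical boundary
    from the charge-hydropathy literature.
    """

    slope: float = 2.785
    intercept: float = -1.151

    def classify(self, mean_abs_net_charge: float, mean_scaled_hydropathy: float) -> str:
        if mean_abs_net_charge >= self.slope * mean_scaled_hydropathy + self.intercept:
            return "disordered_like"
        return "folded_like"


# ---------------------------------------------------------------------------
# result types


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of one residue type.

    ``start`` is 1-based inclusive in full-protein coordinates; the run
    covers ``start .. start + length - 1``.
    """

    residue: str
    start: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass(frozen=True)
class MotifHit:
    """A single self-association motif occurrence."""

    motif_class: str
    start: int
    end: int
    matched: str


@dataclass(frozen=True)
class ChargeHydropathyPoint:
    """A protein's position on the charge-hydropathy plane."""

    mean_abs_net_charge_per_residue: float
    mean_scaled_hydropathy: float
    classification: str


# ---------------------------------------------------------------------------
# helpers


def _check_residue_arg(residue: str) -> str:
    if not (isinstance(residue, str) and len(residue) == 1 and residue in CANONICAL):
        raise SequenceError(f"residue must be one canonical letter, got {residue!r}")
    return residue


def _canonical_counts(record: ProteinRecord) -> Counter:
    return Counter(c for c in record.sequence if c in CANONICAL)


# ---------------------------------------------------------------------------
# operations


def find_homopolymer_runs(record: ProteinRecord, residue: str,
                          min_length: int = 1) -> list[HomopolymerRun]:
    """All maximal runs of ``residue`` with length >= ``min_length``.

    Runs are maximal (flanked by a different letter or a sequence end;
    ambiguous letters break runs), non-overlapping, and returned in
    ascending start order with starts in full-protein coordinates.
    """
    _check_residue_arg(residue)
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    runs: list[HomopolymerRun] = []
    for m in re.finditer(re.escape(residue) + "+", record.sequence):
        length = m.end() - m.start()
        if length >= min_length:
            runs.append(HomopolymerRun(residue=residue,
                                       start=m.start() + record.numbering_offset,
                                       length=length))
    return runs


def max_run_length(record: ProteinRecord, residue: str) -> int:
    """Length of the longest maximal run of ``residue``; 0 if absent."""
    runs = find_homopolymer_runs(record, residue, min_length=1)
    return max((r.length for r in runs), default=0)


def hydropathy_profile(record: ProteinRecord, scale: ResidueScale | None = None,
                       window: int = 9) -> pd.Series:
    """Centered moving average of per-residue scale values.

    Parameters
    ----------
    scale :
        Defaults to the Kyte-Doolittle hydropathy scale.
    window :
        Odd window size; the ``(window-1)/2`` residues at each edge, and any
        position whose window covers an ambiguous letter, carry NaN.

    Returns
    -------
    pandas.Series
        Indexed by full-protein residue number (index name
        ``residue_number``), named after the scale.
    """
    if scale is None:
        scale = kyte_doolittle()
    n = len(record)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if not 1 <= window <= n:
        raise ValueError(f"window {window} does not fit sequence of length {n}")
    values = pd.Series(
        [scale.values.get(c, np.nan) for c in record.sequence],
        index=pd.Index(record.residue_numbers, name="residue_number"),
        name=scale.name, dtype=float,
    )
    return values.rolling(window, center=True, min_periods=window).mean()


def formal_net_charge(record: ProteinRecord,
                      convention: ChargeConvention | None = None) -> int:
    """Formal net charge from residue counts: (#K + #R) - (#D + #E).

    Histidine is neutral under the default convention; termini are ignored.
    """
    convention = convention or ChargeConvention()
    counts = _canonical_counts(record)
    pos = sum(counts[c] for c in convention.positive)
    neg = sum(counts[c] for c in convention.negative)
    return pos - neg


def charge_hydropathy_point(record: ProteinRecord,
                            scale: ResidueScale | None = None,
                            boundary: BoundaryLine | None = None,
                            convention: ChargeConvention | None = None,
                            ) -> ChargeHydropathyPoint:
    """Place a protein on the charge-hydropathy plane and classify it.

    The coordinates are composition-only statistics: mean absolute formal
    net charge per residue, and the mean of min-max-scaled (0..1) hydropathy
    values.  Ambiguous letters are excluded from both numerator and
    denominator.
    """
    if scale is None:
        scale = kyte_doolittle()
    boundary = boundary or BoundaryLine()
    counts = _canonical_counts(record)
    n = sum(counts.values())
    if n == 0:
        raise SequenceError("no canonical residues in record")
    r = abs(formal_net_charge(record, convention)) / n
    scaled = scale.scaled().values
    h = sum(scaled[c] * k for c, k in counts.items()) / n
    return ChargeHydropathyPoint(
        mean_abs_net_charge_per_residue=r,
        mean_scaled_hydropathy=h,
        classification=boundary.classify(r, h),
    )


# ---------------------------------------------------------------------------
# motif scanning

#: Motif classes with regex-expressible defaults (QN_rich is density-based).
MOTIF_CLASSES = ("SR_repeat", "RG_RGG", "GS_Y_GS", "QN_rich")


@dataclass(frozen=True)
class MotifConfig:
    """Definitions of the four self-association motif classes.

    Defaults:

    * ``SR_repeat`` -- at least two consecutive SR or RS dipeptides.
    * ``RG_RGG`` -- an RGG tripeptide, or an isolated RG flanked by glycine.
    * ``GS_Y_GS`` -- ``[GS]Y[GS]``; the aromatic position is configurable
      (set ``gs_aromatics="FYW"`` for the broader [G/S]-[F/Y/W]-[G/S] class
      seen in other RNA-binding-protein IDRs).
    * ``QN_rich`` -- any window of ``qn_window`` residues containing at
      least ``qn_min_count`` Q/N; overlapping qualifying windows are merged
      into one maximal hit.
    """

    sr_min_dipeptides: int = 2
    gs_aromatics: str = "Y"
    qn_window: int = 10
    qn_min_count: int = 6

    def regex(self, motif_class: str) -> re.Pattern | None:
        if motif_class == "SR_repeat":
            return re.compile(r"(?:SR|RS){%d,}" % self.sr_min_dipeptides)
        if motif_class == "RG_RGG":
            return re.compile(r"RGG|(?<=G)RG")
        if motif_class == "GS_Y_GS":
            return re.compile(r"[GS][%s][GS]" % self.gs_aromatics)
        return None  # QN_rich is handled by the density rule


def _qn_rich_hits(record: ProteinRecord, cfg: MotifConfig) -> list[MotifHit]:
    seq, w, k = record.sequence, cfg.qn_window, cfg.qn_min_count
    if len(seq) < w:
        return []
    is_qn = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_qn = ((is_qn == ord("Q")) | (is_qn == ord("N"))).astype(int)
    win = np.convolve(is_qn, np.ones(w, dtype=int), mode="valid")
    qualifying = np.flatnonzero(win >= k)  # 0-based window starts
    hits: list[MotifHit] = []
    for start in qualifying:
        end = start + w - 1  # inclusive, 0-based
        if hits and start <= hits[-1].end - record.numbering_offset:
            merged_end = max(hits[-1].end, end + record.numbering_offset)
            prev = hits[-1]
            hits[-1] = MotifHit(
                motif_class="QN_rich", start=prev.start, end=merged_end,
                matched=seq[prev.start - record.numbering_offset:
                            merged_end - record.numbering_offset + 1])
        else:
            hits.append(MotifHit(
                motif_class="QN_rich",
                start=start + record.numbering_offset,
                end=end + record.numbering_offset,
                matched=seq[start:end + 1]))
    return hits


def scan_motifs(record: ProteinRecord,
                classes: Iterable[str] = MOTIF_CLASSES,
                config: MotifConfig | None = None) -> list[MotifHit]:
    """Scan for self-association motifs.

    Returns all non-overlapping hits (per class, left-to-right maximal
    matching) in ascending start order; hits of different classes may
    overlap each other.
    """
    cfg = config or MotifConfig()
    classes = list(classes)
    unknown = sorted(set(classes) - set(MOTIF_CLASSES))
    if unknown:
        raise ValueError(f"unknown motif classes: {unknown}")
    hits: list[MotifHit] = []
    for cls in classes:
        if cls == "QN_rich":
            hits.extend(_qn_rich_hits(record, cfg))
            continue
        pattern = cfg.regex(cls)
        for m in pattern.finditer(record.sequence):
            hits.append(MotifHit(
                motif_class=cls,
                start=m.start() + record.numbering_offset,
                end=m.end() - 1 + record.numbering_offset,
                matched=m.group()))
    return sorted(hits, key=lambda h: (h.start, h.motif_class))


def complexity_profile(record: ProteinRecord, window: int = 12) -> pd.Series:
    """Shannon entropy (bits) of residue composition per sliding window.

    A low-complexity proxy: windows dominated by few residue types score
    near 0 bits, maximally mixed windows score up to log2(window).  The
    series is indexed by the full-protein residue number of each window
    *start*; windows containing ambiguous letters score NaN.
    """
    seq, n = record.sequence, len(record)
    if not 1 <= window <= n:
        raise ValueError(f"window {window} does not fit sequence of length {n}")
    starts = range(n - window + 1)
    out = np.empty(len(starts))
    for i in starts:
        chunk = seq[i:i + window]
        if any(c in AMBIGUOUS for c in chunk):
            out[i] = np.nan
            continue
        counts = np.array(list(Counter(chunk).values()), dtype=float)
        p = counts / window
        out[i] = float(-(p * np.log2(p)).sum())
    index = pd.Index(
        [s + record.numbering_offset for s in starts], name="residue_number")
    return pd.Series(out, index=index, name="entropy_bits")


def composition_fraction(record: ProteinRecord, residues: Iterable[str]) -> float:
    """Percentage of canonical residues belonging to ``residues``.

    The denominator is the number of canonical residues, so the twenty
    single-residue fractions always sum to 100%.
    """
    residues = {(_check_residue_arg(r)) for r in residues}
    counts = _canonical_counts(record)
    n = sum(counts.values())
    if n == 0:
        raise SequenceError("no canonical residues in record")
    return 100.0 * sum(counts[r] for r in residues) / n
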