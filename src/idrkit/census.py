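"""Proteome-scale polyalanine-tract census.

For each alanine-run length k (default bins 5..20) the census asks: of the
proteins whose longest poly-A tract has length k, what fraction carries an
RNA-related (or specifically "RNA binding") annotation, and how does that
fraction compare with the proteome-wide background?  Enrichment above 1
indicates an association between polyalanine tracts and RNA function.
Uncertainty comes from protein-level bootstrap resampling.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import ProteinRecord
from .seqfeat import max_run_length

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationRecord", "KeywordPolicy", "CensusResult",
    "RNA_RELATED", "RNA_BINDING",
    "classify_positive", "run_census", "census_report", "read_census_report",
    "read_annotations", "write_annotations",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """An accession with its annotation terms (GO names and/or keywords)."""

    id: str
    terms: tuple[str, ...]

    def __init__(self, id: str, terms: Iterable[str]):
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "terms", tuple(terms))


@dataclass(frozen=True)
class KeywordPolicy:
    """What counts as an annotation-positive protein.

    ``match="substring"`` flags a protein when any term contains any pattern
    (case-insensitive); ``match="exact"`` requires case-insensitive term
    equality.  Two policies ship as module constants: :data:`RNA_RELATED`
    (any term containing "RNA": covers RNA binding, RNA polymerase, mRNA
    processing, rRNA/tRNA terms, ...) and :data:`RNA_BINDING` (the exact
    term "RNA binding").
    """

    mode: str
    patterns: tuple[str, ...]
    match: str = "substring"

    def __post_init__(self) -> None:
        if not self.patterns:
            raise ValueError("KeywordPolicy.patterns must be non-empty")
        if self.match not in ("substring", "exact"):
            raise ValueError(f"unknown match kind {self.match!r}")
        object.__setattr__(self, "patterns", tuple(self.patterns))


RNA_RELATED = KeywordPolicy(mode="rna_related", patterns=("RNA",),
                            match="substring")
RNA_BINDING = KeywordPolicy(mode="rna_binding", patterns=("RNA binding",),
                            match="exact")


def classify_positive(record: AnnotationRecord, policy: KeywordPolicy) -> bool:
    """True iff any annotation term matches any policy pattern."""
    patterns = [p.lower() for p in policy.patterns]
    for term in record.terms:
        t = term.lower()
        if policy.match == "substring":
            if any(p in t for p in patterns):
                return True
        else:
            if any(p == t for p in patterns):
                return True
    return False


# ---------------------------------------------------------------------------


@dataclass
class CensusResult:
    """Per-run-length proportions of annotation-positive proteins.

    ``enrichment[k] = proportion[k] / background_proportion``; bins with no
    proteins (or a zero background) carry NaN.  ``ci_low``/``ci_high`` are
    percentile bootstrap bounds on the enrichment (NaN when bootstrap was
    skipped or the bin was empty in too many resamples).
    """

    run_length_bins: np.ndarray
    n_with_tract: np.ndarray
    n_positive_with_tract: np.ndarray
    proportion: np.ndarray
    background_proportion: float
    enrichment: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_proteins: int
    bin_mode: str
    policy_mode: str
    n_bootstrap: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "run_length": self.run_length_bins,
            "n_with_tract": self.n_with_tract,
            "n_positive_with_tract": self.n_positive_with_tract,
            "proportion": self.proportion,
            "enrichment": self.enrichment,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        })


def _collapse_isoform(accession: str) -> str:
    return re.sub(r"-\d+$", "", accession)


def _bin_counts(maxrun: np.ndarray, positive: np.ndarray,
                bins: np.ndarray, bin_mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Counts (n_with_tract, n_positive) per bin for one (re)sample."""
    top = bins.max()
    clipped = np.minimum(maxrun, top + 1)
    counts = np.bincount(clipped, minlength=top + 2)
    pos_counts = np.bincount(clipped[positive], minlength=top + 2)
    if bin_mode == "exact_max_run":
        return counts[bins], pos_counts[bins]
    # at_least: cumulative from the top, including runs longer than the last bin
    rev = np.cumsum(counts[::-1])[::-1]
    rev_pos = np.cumsum(pos_counts[::-1])[::-1]
    return rev[bins], rev_pos[bins]


def run_census(proteome: Sequence[ProteinRecord],
               annotations: Iterable[AnnotationRecord] | Mapping[str, Sequence[str]],
               policy: KeywordPolicy = RNA_RELATED,
               bins: Iterable[int] = range(5, 21),
               bin_mode: str = "exact_max_run",
               n_bootstrap: int = 1000,
               seed: int | None = None,
               collapse_isoforms: bool = True,
               residue: str = "A") -> CensusResult:
    """Run the polyalanine census over a proteome.

    Parameters
    ----------
    proteome :
        Protein records; duplicated accessions are dropped (first kept).
    annotations :
        AnnotationRecords or a mapping accession -> terms.  Proteome ids
        missing from the table are warned about and treated as negative.
    bin_mode :
        ``"exact_max_run"`` assigns each protein to the bin of its longest
        A-run (proteins counted once); ``"at_least"`` counts a protein in
        every bin up to its longest run (substring-search semantics).
    n_bootstrap, seed :
        Protein-level percentile bootstrap for enrichment CIs.  A seed is
        required whenever ``n_bootstrap > 0``.
    """
    if not proteome:
        raise ValueError("empty proteome")
    bins = np.asarray(sorted(set(int(b) for b in bins)), dtype=int)
    if bins.min() < 1:
        raise ValueError("run-length bins must be >= 1")
    max_len = max(len(p) for p in proteome)
    if bins.min() > max_len:
        raise ValueError(f"smallest bin {bins.min()} exceeds longest sequence ({max_len})")
    if bin_mode not in ("exact_max_run", "at_least"):
        raise ValueError(f"unknown bin_mode {bin_mode!r}")
    if n_bootstrap > 0 and seed is None:
        raise ValueError("a seed is required when bootstrapping")

    if isinstance(annotations, Mapping):
        ann = {k: tuple(v) for k, v in annotations.items()}
    else:
        ann = {a.id: a.terms for a in annotations}
    if collapse_isoforms:
        collapsed = {}
        for k, v in ann.items():
            collapsed.setdefault(_collapse_isoform(k), v)
        ann = collapsed

    seen: set[str] = set()
    maxruns: list[int] = []
    positives: list[bool] = []
    missing = 0
    for rec in proteome:
        acc = _collapse_isoform(rec.id) if collapse_isoforms else rec.id
        if acc in seen:
            continue
        seen.add(acc)
        maxruns.append(max_run_length(rec, residue))
        if acc in ann:
            positives.append(classify_positive(
                AnnotationRecord(acc, ann[acc]), policy))
        else:
            missing += 1
            positives.append(False)
    if missing:
        warnings.warn(f"{missing} proteome ids missing from the annotation "
                      "table; treated as annotation-negative", stacklevel=2)

    maxrun = np.asarray(maxruns, dtype=int)
    positive = np.asarray(positives, dtype=bool)
    n = len(maxrun)

    background = positive.mean()
    n_with, n_pos = _bin_counts(maxrun, positive, bins, bin_mode)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportion = np.where(n_with > 0, n_pos / np.maximum(n_with, 1), np.nan)
        enrichment = proportion / background if background > 0 else np.full_like(proportion, np.nan)

    ci_low = np.full(bins.shape, np.nan)
    ci_high = np.full(bins.shape, np.nan)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_bootstrap, len(bins)))
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            mr, pos = maxrun[idx], positive[idx]
            bg = pos.mean()
            nw, npos = _bin_counts(mr, pos, bins, bin_mode)
            with np.errstate(invalid="ignore", divide="ignore"):
                prop = np.where(nw > 0, npos / np.maximum(nw, 1), np.nan)
                boot[b] = prop / bg if bg > 0 else np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            ci_low = np.nanpercentile(boot, 2.5, axis=0)
            ci_high = np.nanpercentile(boot, 97.5, axis=0)
        empty_often = np.isnan(boot).mean(axis=0) > 0.5
        ci_low[empty_often] = np.nan
        ci_high[empty_often] = np.nan

    return CensusResult(
        run_length_bins=bins, n_with_tract=n_with, n_positive_with_tract=n_pos,
        proportion=proportion, background_proportion=float(background),
        enrichment=enrichment, ci_low=ci_low, ci_high=ci_high,
        n_proteins=n, bin_mode=bin_mode, policy_mode=policy.mode,
        n_bootstrap=n_bootstrap, seed=seed)


# ---------------------------------------------------------------------------
# reporting / serialization


def census_report(result: CensusResult, path: str | Path | None = None,
                  fmt: str = "tsv") -> pd.DataFrame:
    """One row per bin, bar-chart ready; undefined enrichments stay null.

    With ``path`` the table is written as TSV (NaN -> empty field) or, with
    ``fmt="json"``, as a JSON document that also carries the scalar census
    metadata (background proportion, proteome size, modes, seed).
    """
    frame = result.to_frame()
    if path is not None:
        path = Path(path)
        if fmt == "tsv":
            frame.to_csv(path, sep="\t", index=False)
        elif fmt == "json":
            payload = {
                "background_proportion": result.background_proportion,
                "n_proteins": result.n_proteins,
                "bin_mode": result.bin_mode,
                "policy_mode": result.policy_mode,
                "n_bootstrap": result.n_bootstrap,
                "seed": result.seed,
                "bins": json.loads(frame.to_json(orient="records")),
            }
            path.write_text(json.dumps(payload, indent=2) + "\n")
        else:
            raise ValueError(f"unknown report format {fmt!r}")
    return frame


def read_census_report(path: str | Path) -> pd.DataFrame:
    """Read back a TSV census report (empty fields -> NaN)."""
    return pd.read_csv(path, sep="\t")


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read an annotation TSV: ``accession<TAB>semicolon-joined terms``."""
    out: list[AnnotationRecord] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        acc = parts[0]
        terms = [t.strip() for t in parts[1].split(";") if t.strip()] if len(parts) > 1 else []
        out.append(AnnotationRecord(acc, terms))
    return out


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    lines = [f"{r.id}\t{'; '.join(r.terms)}" for r in records]
    Path(path).write_text("\n".join(lines) + "\n")
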