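"""Synthetic-data generators with the statistical structure the analyses assume.

Three generators cover the pipeline's inputs so every stage is testable
without downloads:

* :func:`generate_proteome` -- a proteome FASTA plus annotation TSV with
  poly-A tracts of controlled lengths planted into a human-like background
  composition, and RNA-relatedness labels at a controlled enrichment.
* :func:`generate_shift_table` -- backbone chemical shifts from a two-state
  helix-coil mixture (coil reference plus population-weighted full-helix
  offsets plus noise).
* :func:`generate_decay_curves` -- mono-exponential relaxation decays with
  multiplicative Gaussian noise.

All generators are pure functions of their spec and seed: the same seed
yields byte-identical outputs.  Each returns a ground-truth table so
recovery can be measured end to end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .census import AnnotationRecord
from .datasets import background_frequencies, random_coil_table
from .nmr import DEFAULT_DELAYS, RelaxationSeries
from .records import ProteinRecord
from .seqfeat import max_run_length

logger = logging.getLogger(__name__)

__all__ = [
    "ProteomeSimSpec", "ShiftSimSpec",
    "generate_proteome", "generate_shift_table", "generate_decay_curves",
    "RNA_TERMS", "NON_RNA_TERMS", "FULL_HELIX_OFFSETS",
]

#: Annotation vocabularies used to label synthetic proteins.  The positive
#: list mimics RNA-related GO names/keywords; the negative list deliberately
#: contains no "RNA" substring.
RNA_TERMS = ("RNA binding", "mRNA processing", "rRNA processing",
             "tRNA aminoacylation", "RNA polymerase II activity",
             "mRNA splicing via spliceosome")
NON_RNA_TERMS = ("protein folding", "lipid metabolic process",
                 "cell adhesion", "ion transport", "proteolysis",
                 "signal transduction", "DNA repair", "cytoskeleton organization")

#: Full-helix secondary-shift offsets (ppm) for the two-state shift model:
#: a residue that is helical 100% of the time deviates from coil by these.
FULL_HELIX_OFFSETS = {"CA": 2.8, "CB": -0.5, "C": 1.1}


@dataclass(frozen=True)
class ProteomeSimSpec:
    """Specification of a synthetic annotated proteome.

    Defaults emulate a reviewed human proteome at reduced scale: ~2000
    proteins with lognormal lengths (median ~370 residues), human-like
    background composition, an RNA-related annotation rate of 20.3%, and
    poly-A tracts of lengths 5-10 planted into 40 proteins each whose
    positive rate is doubled (enrichment factor 2.0).
    """

    n_proteins: int = 2000
    length_log_mean: float = 5.91   # exp(5.91) ~ 369 residues
    length_log_sd: float = 0.55
    min_length: int = 60
    composition: Mapping[str, float] | None = None
    tract_spec: Mapping[int, int] = field(
        default_factory=lambda: {k: 40 for k in range(5, 11)})
    positive_rate_background: float = 0.203
    enrichment_factor: Mapping[int, float] = field(
        default_factory=lambda: {k: 2.0 for k in range(5, 11)})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if not 0 <= self.positive_rate_background <= 1:
            raise ValueError("positive_rate_background must lie in [0, 1]")
        if sum(self.tract_spec.values()) > self.n_proteins:
            raise ValueError("more planted tracts than proteins")
        for k, f in self.enrichment_factor.items():
            if self.positive_rate_background * f > 1:
                warnings.warn(
                    f"enrichment factor {f} at run length {k} caps the "
                    "positive rate at 1", stacklevel=2)


def _random_sequence(rng: np.random.Generator, length: int,
                     letters: np.ndarray, probs: np.ndarray) -> str:
    return "".join(rng.choice(letters, size=length, p=probs))


def _plant_tract(rng: np.random.Generator, seq: str, run_length: int) -> str:
    """Insert an exact-length A-run at a position not adjacent to an A."""
    if run_length >= len(seq):
        raise ValueError(
            f"tract of length {run_length} does not fit protein of length {len(seq)}")
    for _ in range(1000):
        pos = int(rng.integers(0, len(seq) + 1))
        left = seq[pos - 1] if pos > 0 else ""
        right = seq[pos] if pos < len(seq) else ""
        if left != "A" and right != "A":
            return seq[:pos] + "A" * run_length + seq[pos:]
    raise RuntimeError("could not place tract away from existing alanines")


def generate_proteome(spec: ProteomeSimSpec,
                      ) -> tuple[list[ProteinRecord], list[AnnotationRecord], pd.DataFrame]:
    """Generate (proteome, annotations, truth table) from a spec.

    The truth table records, per protein, the planted run length (0 when
    none), the realized maximal A-run (which can exceed the planted length
    by background chance elsewhere in the sequence), and the positive
    label.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    comp = dict(spec.composition or background_frequencies())
    letters = np.array(list(comp.keys()))
    probs = np.array(list(comp.values()), dtype=float)
    probs = probs / probs.sum()

    lengths = np.maximum(
        rng.lognormal(spec.length_log_mean, spec.length_log_sd,
                      spec.n_proteins).astype(int),
        spec.min_length)

    planted = np.zeros(spec.n_proteins, dtype=int)
    slots = rng.permutation(spec.n_proteins)
    cursor = 0
    for run_length, count in sorted(spec.tract_spec.items()):
        for _ in range(count):
            planted[slots[cursor]] = run_length
            cursor += 1

    records: list[ProteinRecord] = []
    annotations: list[AnnotationRecord] = []
    truth_rows = []
    width = len(str(spec.n_proteins))
    for i in range(spec.n_proteins):
        seq = _random_sequence(rng, int(lengths[i]), letters, probs)
        if planted[i]:
            seq = _plant_tract(rng, seq, int(planted[i]))
        acc = f"SYN{i:0{width}d}"
        rec = ProteinRecord(acc, seq)
        rate = spec.positive_rate_background
        if planted[i]:
            rate = min(rate * spec.enrichment_factor.get(int(planted[i]), 1.0), 1.0)
        positive = bool(rng.random() < rate)
        if positive:
            terms = [str(rng.choice(RNA_TERMS))]
            terms += list(rng.choice(NON_RNA_TERMS,
                                     size=int(rng.integers(0, 3)), replace=False))
        else:
            terms = list(rng.choice(NON_RNA_TERMS,
                                    size=int(rng.integers(1, 4)), replace=False))
        records.append(rec)
        annotations.append(AnnotationRecord(acc, terms))
        truth_rows.append((acc, len(seq), int(planted[i]),
                           max_run_length(rec, "A"), positive))

    truth = pd.DataFrame(
        truth_rows,
        columns=["id", "length", "planted_run", "max_a_run", "positive"])
    return records, annotations, truth


# ---------------------------------------------------------------------------
# chemical shifts


@dataclass(frozen=True)
class ShiftSimSpec:
    """Two-state helix-coil chemical-shift model for one sequence.

    ``helix_segments`` maps inclusive full-protein residue ranges to helical
    populations p in [0, 1]; everywhere else p = 0.  Observed shifts are
    ``coil + p * full_helix_offset + N(0, noise_sd)`` per atom.
    """

    record: ProteinRecord
    helix_segments: tuple[tuple[int, int, float], ...] = ()
    offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(FULL_HELIX_OFFSETS))
    noise_sd: Mapping[str, float] = field(
        default_factory=lambda: {"CA": 0.0, "CB": 0.0, "C": 0.0})
    seed: int = 0

    def __post_init__(self) -> None:
        numbers = self.record.residue_numbers
        for start, end, p in self.helix_segments:
            if start not in numbers or end not in numbers or end < start:
                raise ValueError(
                    f"helix segment {start}-{end} outside sequence range "
                    f"{numbers.start}-{numbers.stop - 1}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"helical population {p} outside [0, 1]")


def generate_shift_table(spec: ShiftSimSpec) -> pd.DataFrame:
    """Synthesize a long-format chemical-shift table (CA/CB/C).

    Glycine contributes no CB row.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rc = random_coil_table()
    populations = {}
    for start, end, p in spec.helix_segments:
        for num in range(start, end + 1):
            populations[num] = p
    rows = []
    for num in spec.record.residue_numbers:
        letter = spec.record.residue_at(num)
        if letter not in rc.index:
            continue
        p = populations.get(num, 0.0)
        for atom in ("CA", "CB", "C"):
            ref = rc.loc[letter, atom]
            if pd.isna(ref):
                continue
            noise = rng.normal(0.0, spec.noise_sd.get(atom, 0.0)) \
                if spec.noise_sd.get(atom, 0.0) > 0 else 0.0
            rows.append((num, letter, atom,
                         float(ref) + p * spec.offsets.get(atom, 0.0) + noise))
    return pd.DataFrame(rows, columns=["residue_number", "residue", "atom",
                                       "shift_ppm"])


# ---------------------------------------------------------------------------
# relaxation decays


def generate_decay_curves(n_residues: int = 200,
                          r2_range: tuple[float, float] = (5.0, 30.0),
                          noise_rel: float = 0.02,
                          delays: Sequence[float] = DEFAULT_DELAYS,
                          seed: int = 0,
                          i0_range: tuple[float, float] = (0.5, 2.0),
                          ) -> tuple[RelaxationSeries, pd.DataFrame]:
    """Mono-exponential decay curves with multiplicative Gaussian noise.

    ``I(t) = I0 * exp(-R2 t) * (1 + eps)``, ``eps ~ N(0, noise_rel)``, with
    true R2 drawn uniformly from ``r2_range``.  The returned series carries
    a per-point noise estimate (``noise_rel`` times the observed intensity)
    and a truth table of (I0, R2) per residue.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(delays, dtype=float)
    r2 = rng.uniform(*r2_range, n_residues)
    i0 = rng.uniform(*i0_range, n_residues)
    clean = i0[:, None] * np.exp(-r2[:, None] * t[None, :])
    observed = clean * (1.0 + rng.normal(0.0, noise_rel, clean.shape)) \
        if noise_rel > 0 else clean
    index = pd.RangeIndex(1, n_residues + 1, name="residue_number")
    intensities = pd.DataFrame(observed, index=index,
                               columns=[f"t_{x:g}" for x in t])
    noise = pd.DataFrame(noise_rel * np.abs(observed), index=index,
                         columns=intensities.columns) if noise_rel > 0 else None
    truth = pd.DataFrame({"I0": i0, "R2": r2}, index=index)
    return RelaxationSeries(tuple(t), intensities, noise=noise), truth
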