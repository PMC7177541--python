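"""Residue-resolved NMR analytics for disordered proteins.

Four stages, matching a typical self-association study of an IDR:

* **Secondary chemical shifts** -- observed backbone shifts minus
  random-coil references; positive Ca (and C') deviations flag transient
  helix.
* **Helical population** -- a simple two-state estimate from the mean Ca
  secondary shift of a region against the full-helix limit (~2.8 ppm).
* **Intensity ratios** -- per-residue HSQC peak-intensity ratios between a
  concentrated and a dilute sample; ratios below the molar ratio indicate
  concentration-dependent line broadening, i.e. self-association.
* **R2 fitting** -- mono-exponential fits of peak intensity versus
  relaxation delay with Monte-Carlo error propagation.

Table schemas are thin pandas DataFrames so the module composes naturally
with TSV inputs and with the synthetic generators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datasets import random_coil_table
from .records import ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SHIFT_ATOMS", "DEFAULT_REGIONS", "DEFAULT_DELAYS",
    "PeakIntensityTable", "RelaxationSeries", "IntensityRatioResult",
    "read_shift_table", "write_shift_table",
    "secondary_shifts", "helical_population",
    "intensity_ratio", "fit_r2", "broadening_flags",
]

SHIFT_ATOMS = ("CA", "CB", "C", "H", "N", "HN")

#: Transient-helix regions of the Musashi-1 IDR (full-protein numbering,
#: inclusive).  Endpoints are approximate in the underlying data
#: ("~208-218", "~270-284") and freely overridable.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "helix1": (208, 218),
    "helix2": (270, 284),
}

#: Relaxation delays (seconds) of the standard R2 experiment this package's
#: fixtures assume.
DEFAULT_DELAYS: tuple[float, ...] = (0.0172, 0.0343, 0.0515, 0.0686, 0.1201, 0.1544)


# ---------------------------------------------------------------------------
# chemical-shift tables


def _validate_shift_table(df: pd.DataFrame) -> pd.DataFrame:
    required = {"residue_number", "residue", "atom", "shift_ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"shift table missing columns: {sorted(missing)}")
    bad_atoms = set(df["atom"]) - set(SHIFT_ATOMS)
    if bad_atoms:
        raise ValueError(f"unknown atoms in shift table: {sorted(bad_atoms)}")
    dup = df.duplicated(subset=["residue_number", "atom"])
    if dup.any():
        pairs = df.loc[dup, ["residue_number", "atom"]].values.tolist()
        raise ValueError(f"duplicate (residue, atom) rows: {pairs[:5]}")
    return df


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Read a chemical-shift TSV (residue_number, residue, atom, shift_ppm)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return _validate_shift_table(df)


def write_shift_table(df: pd.DataFrame, path: str | Path) -> None:
    _validate_shift_table(df).to_csv(path, sep="\t", index=False)


def secondary_shifts(obs: pd.DataFrame,
                     rc: pd.DataFrame | None = None,
                     record: ProteinRecord | None = None,
                     atoms: Sequence[str] = ("CA", "CB", "C")) -> pd.DataFrame:
    """Secondary chemical shifts: observed minus random-coil reference.

    Parameters
    ----------
    obs :
        Long-format shift table (``residue_number, residue, atom,
        shift_ppm``).
    rc :
        Random-coil reference, indexed by residue letter with one column
        per atom; defaults to the packaged table.
    record :
        Optional sequence cross-check: each table row's residue letter must
        match the record at that position (mismatch raises, naming the
        position).

    Returns
    -------
    pandas.DataFrame
        Indexed by ``residue_number`` with a ``residue`` column and one
        ``delta_<atom>`` column per requested atom; NaN where either the
        observation or the reference is missing.
    """
    obs = _validate_shift_table(obs)
    rc = random_coil_table() if rc is None else rc
    if record is not None:
        for num, letter in obs[["residue_number", "residue"]].drop_duplicates().values:
            expected = record.residue_at(int(num))
            if letter != expected:
                raise ValueError(
                    f"residue mismatch at position {num}: table says {letter}, "
                    f"sequence says {expected}")
    sub = obs[obs["atom"].isin(atoms)].copy()
    ref = rc.reindex(sub["residue"].values)
    ref_vals = np.array([ref.iloc[i][a] if a in ref.columns else np.nan
                         for i, a in enumerate(sub["atom"].values)])
    sub["delta"] = sub["shift_ppm"].to_numpy(dtype=float) - ref_vals
    wide = sub.pivot(index="residue_number", columns="atom", values="delta")
    wide = wide.reindex(columns=list(atoms))
    wide.columns = [f"delta_{a}" for a in wide.columns]
    letters = obs.drop_duplicates("residue_number").set_index("residue_number")["residue"]
    wide.insert(0, "residue", letters.reindex(wide.index))
    return wide


def helical_population(profile: pd.DataFrame,
                       region: tuple[int, int],
                       full_helix_delta_ca: float = 2.8) -> float:
    """Two-state helix population from mean Ca secondary shift over a region.

    ``mean(delta_CA) / full_helix_delta_ca`` clipped to [0, 1].  The region
    is inclusive in full-protein numbering and must contribute at least
    three defined Ca secondary shifts.  This is a deliberately simple
    estimator; multi-state chemical-shift deconvolution is out of scope.
    """
    lo, hi = region
    if hi < lo:
        raise ValueError(f"empty region {region}")
    sel = profile.loc[(profile.index >= lo) & (profile.index <= hi), "delta_CA"]
    sel = sel.dropna()
    if len(sel) < 3:
        raise ValueError(
            f"region {lo}-{hi} has only {len(sel)} defined Ca secondary shifts (need >= 3)")
    return float(np.clip(sel.mean() / full_helix_delta_ca, 0.0, 1.0))


# ---------------------------------------------------------------------------
# intensity ratios


@dataclass(frozen=True)
class PeakIntensityTable:
    """Per-residue peak intensities at one stated sample condition."""

    data: pd.DataFrame  # columns: residue_number, intensity
    concentration_um: float
    temperature_k: float | None = None
    ph: float | None = None

    def __post_init__(self) -> None:
        required = {"residue_number", "intensity"}
        if not required <= set(self.data.columns):
            raise ValueError(f"intensity table needs columns {sorted(required)}")
        if (self.data["intensity"].dropna() < 0).any():
            raise ValueError("negative intensities")
        if not self.concentration_um > 0:
            raise ValueError("concentration_um must be positive")

    def series(self) -> pd.Series:
        return self.data.set_index("residue_number")["intensity"].astype(float)


@dataclass(frozen=True)
class IntensityRatioResult:
    """Per-residue concentration intensity ratios and their means."""

    ratios: pd.Series
    mean: float
    region_means: dict[str, float]
    molar_ratio: float
    n_skipped: int


def intensity_ratio(high: PeakIntensityTable, low: PeakIntensityTable,
                    regions: Mapping[str, tuple[int, int]] | None = None,
                    ) -> IntensityRatioResult:
    """Per-residue I_high / I_low with overall and per-region means.

    Residues where either intensity is missing or non-positive are skipped
    (and counted in ``n_skipped``).  The molar ratio of the two sample
    concentrations is reported alongside: under ideal dilution scaling the
    intensity ratio equals the molar ratio, and self-association pulls it
    below.
    """
    if regions is None:
        regions = DEFAULT_REGIONS
    hi, lo = high.series(), low.series()
    index = hi.index.intersection(lo.index)
    h, l = hi.reindex(index), lo.reindex(index)
    usable = (h > 0) & (l > 0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("intensity_ratio: skipped %d residues with missing or "
                    "non-positive intensities", n_skipped)
    ratios = (h[usable] / l[usable]).rename("intensity_ratio")
    region_means = {}
    for name, (a, b) in regions.items():
        sel = ratios[(ratios.index >= a) & (ratios.index <= b)]
        region_means[name] = float(sel.mean()) if len(sel) else float("nan")
    return IntensityRatioResult(
        ratios=ratios,
        mean=float(ratios.mean()) if len(ratios) else float("nan"),
        region_means=region_means,
        molar_ratio=high.concentration_um / low.concentration_um,
        n_skipped=n_skipped)


def broadening_flags(ratios: pd.Series, molar_ratio: float,
                     threshold_fraction: float = 0.5,
                     ) -> tuple[pd.Series, list[tuple[int, int]]]:
    """Flag residues whose intensity ratio falls well below the molar ratio.

    A residue is flagged when ``ratio < threshold_fraction * molar_ratio``;
    maximal contiguous flagged stretches (consecutive residue numbers) are
    returned as (start, end) pairs.
    """
    flags = (ratios < threshold_fraction * molar_ratio).rename("broadened")
    regions: list[tuple[int, int]] = []
    for num in sorted(flags.index[flags]):
        if regions and num == regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], num)
        else:
            regions.append((num, num))
    return flags, regions


# ---------------------------------------------------------------------------
# R2 fitting


@dataclass(frozen=True)
class RelaxationSeries:
    """Intensity-versus-delay curves for many residues.

    ``intensities`` is indexed by residue number with one column per delay
    (column order matching ``delays``).  ``noise`` is an optional intensity
    standard-deviation estimate: a scalar, a per-residue Series, or a
    DataFrame shaped like ``intensities`` for per-point errors.
    """

    delays: tuple[float, ...]
    intensities: pd.DataFrame
    noise: float | pd.Series | pd.DataFrame | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        if len(d) < 3:
            raise ValueError("need at least 3 relaxation delays")
        if not np.all(np.diff(d) > 0):
            raise ValueError("delays must be strictly increasing")
        if self.intensities.shape[1] != len(d):
            raise ValueError("intensity columns must match number of delays")
        object.__setattr__(self, "delays", tuple(float(x) for x in d))


def _exp_decay(t: np.ndarray, i0: float, r2: float) -> np.ndarray:
    return i0 * np.exp(-r2 * t)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    i0 = float(y[0])
    if y[0] > 0 and y[-1] > 0:
        r2 = float(np.log(y[0] / y[-1]) / (t[-1] - t[0]))
    else:
        r2 = 1.0
    return i0, max(r2, 0.0)


def _fit_one(t: np.ndarray, y: np.ndarray,
             sigma: np.ndarray | None) -> tuple[float, float, bool]:
    p0 = _initial_guess(t, y)
    try:
        popt, _ = curve_fit(_exp_decay, t, y, p0=p0, sigma=sigma,
                            absolute_sigma=sigma is not None, maxfev=2000)
        return float(popt[0]), float(popt[1]), True
    except (RuntimeError, ValueError):
        return float("nan"), float("nan"), False


def fit_r2(series: RelaxationSeries, n_mc: int = 500,
           seed: int | None = None) -> pd.DataFrame:
    """Mono-exponential R2 fits with Monte-Carlo error estimates.

    Each residue's curve is fitted to ``I(t) = I0 * exp(-R2 * t)`` by
    nonlinear least squares (initialized from the first point and the
    end-to-end log slope).  Errors: the curve is refit ``n_mc`` times on
    data perturbed by Gaussian noise at the per-point noise level (the
    supplied noise estimate, or the fit-residual RMS when none is given);
    ``sd_R2`` is the standard deviation and ``r2_lo``/``r2_hi`` the
    2.5/97.5 percentiles of the refitted rates.  Deterministic for a given
    seed.  Residues whose primary fit fails are flagged
    (``converged=False``), not fatal.
    """
    if n_mc > 0 and seed is None:
        raise ValueError("a seed is required when n_mc > 0")
    t = np.asarray(series.delays, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for resnum, row in series.intensities.iterrows():
        y = row.to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < 3 or not (y[ok][0] > 0):
            rows.append((resnum, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        tt, yy = t[ok], y[ok]
        sigma = _point_noise(series.noise, resnum, ok, len(t))
        i0, r2, converged = _fit_one(tt, yy, sigma)
        sd = lo = hi = np.nan
        if converged and n_mc > 0:
            if sigma is None:
                resid = yy - _exp_decay(tt, i0, r2)
                dof = max(len(yy) - 2, 1)
                sigma_mc = np.full_like(yy, np.sqrt(np.sum(resid ** 2) / dof))
            else:
                sigma_mc = sigma
            draws = yy + rng.normal(0.0, 1.0, (n_mc, len(yy))) * sigma_mc
            r2s = np.array([_fit_one(tt, d, sigma)[1] for d in draws])
            r2s = r2s[np.isfinite(r2s)]
            if len(r2s):
                sd = float(np.std(r2s, ddof=1))
                lo, hi = (float(x) for x in np.percentile(r2s, [2.5, 97.5]))
        rows.append((resnum, i0, r2, sd, lo, hi, converged))
    out = pd.DataFrame(
        rows, columns=["residue_number", "I0", "R2", "sd_R2",
                       "r2_lo", "r2_hi", "converged"])
    out["n_mc"] = n_mc
    out["seed"] = seed
    return out.set_index("residue_number")


def _point_noise(noise, resnum, ok: np.ndarray, n: int) -> np.ndarray | None:
    if noise is None:
        return None
    if np.isscalar(noise):
        return np.full(int(ok.sum()), float(noise))
    if isinstance(noise, pd.Series):
        return np.full(int(ok.sum()), float(noise.loc[resnum]))
    if isinstance(noise, pd.DataFrame):
        return noise.loc[resnum].to_numpy(dtype=float)[ok]
    raise TypeError(f"unsupported noise spec {type(noise)}")


# ---------------------------------------------------------------------------
# TSV interfaces


def write_intensity_table(table: PeakIntensityTable, path: str | Path) -> None:
    """Write an intensity TSV with a condition header block (# key: value)."""
    lines = [f"# concentration_um: {table.concentration_um:g}"]
    if table.temperature_k is not None:
        lines.append(f"# temperature_k: {table.temperature_k:g}")
    if table.ph is not None:
        lines.append(f"# ph: {table.ph:g}")
    body = table.data[["residue_number", "intensity"]].to_csv(
        sep="\t", index=False)
    Path(path).write_text("\n".join(lines) + "\n" + body)


def read_intensity_table(path: str | Path) -> PeakIntensityTable:
    """Read an intensity TSV written by :func:`write_intensity_table`."""
    meta: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("#"):
            break
        key, _, value = line.lstrip("# ").partition(":")
        meta[key.strip()] = float(value)
    if "concentration_um" not in meta:
        raise ValueError(f"{path}: missing '# concentration_um:' header")
    df = pd.read_csv(path, sep="\t", comment="#")
    return PeakIntensityTable(
        data=df, concentration_um=meta["concentration_um"],
        temperature_k=meta.get("temperature_k"), ph=meta.get("ph"))


def write_relaxation_tsv(series: RelaxationSeries, path: str | Path) -> None:
    """Write a wide relaxation TSV: delays (s) in the column header."""
    df = series.intensities.copy()
    df.columns = [f"{d:g}" for d in series.delays]
    df.to_csv(path, sep="\t", index=True, index_label="residue_number")


def read_relaxation_tsv(path: str | Path,
                        noise: float | None = None) -> RelaxationSeries:
    """Read a wide relaxation TSV (columns = delays in seconds)."""
    df = pd.read_csv(path, sep="\t", index_col="residue_number")
    delays = tuple(float(c) for c in df.columns)
    return RelaxationSeries(delays, df, noise=noise)
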