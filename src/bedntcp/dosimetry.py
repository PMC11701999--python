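"""Linear-quadratic BED conversion and DVH-based dose metrics.

The linear-quadratic (LQ) model makes doses delivered under different
fractionation schedules comparable through the biologically effective dose

    BED = D * (1 + d / (alpha/beta)),

where ``D`` is the total dose a voxel receives, ``d = D / N`` its dose per
fraction under an ``N``-fraction schedule, and ``alpha/beta`` (Gy) the tissue
sensitivity to fraction size (low values = high fractionation sensitivity;
3 Gy is the conventional assumption for late rectal toxicity).

Dose metrics are computed on differential dose-volume histograms (DVHs):

* ``eud`` -- generalized equivalent uniform dose, the power mean
  ``(sum_i v_i D_i^{1/n})^n`` with relative volumes ``v_i``; small volume
  exponents ``n`` emphasise the hottest part of the organ (serial behavior).
* ``v_d`` -- percentage of organ volume receiving at least a threshold dose.
* ``d_xcm3`` -- minimum dose inside the hottest ``x`` cm^3 of the organ.

Because BED is strictly increasing in voxel dose for a fixed schedule and
alpha/beta, transforming the dose axis of a differential DVH bin-by-bin is
exactly equivalent to a voxelwise conversion followed by re-histogramming.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "FractionationScheme",
    "RadiobiologyParams",
    "DVH",
    "DoseMetricSpec",
    "CF_SCHEME",
    "HF_SCHEME",
    "physical_to_bed",
    "bed_transform_dvh",
    "eud",
    "v_d",
    "d_xcm3",
    "compute_metric",
    "alpha_beta_crossover",
    "read_dvh_csv",
    "write_dvh_csv",
]


@dataclass(frozen=True)
class FractionationScheme:
    """A fractionation schedule: total prescribed dose split into equal fractions."""

    n_fractions: int
    prescribed_dose: float  # Gy, total physical dose

    def __post_init__(self) -> None:
        if self.n_fractions < 1 or int(self.n_fractions) != self.n_fractions:
            raise ValueError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        if self.prescribed_dose <= 0:
            raise ValueError(f"prescribed_dose must be > 0, got {self.prescribed_dose}")

    @property
    def dose_per_fraction(self) -> float:
        return self.prescribed_dose / self.n_fractions


#: Conventional fractionation: 78 Gy in 39 fractions of 2 Gy.
CF_SCHEME = FractionationScheme(n_fractions=39, prescribed_dose=78.0)
#: Moderate hypofractionation: 64.6 Gy in 19 fractions of 3.4 Gy.
HF_SCHEME = FractionationScheme(n_fractions=19, prescribed_dose=64.6)


@dataclass(frozen=True)
class RadiobiologyParams:
    """LQ-model tissue parameters; alpha_beta defaults to the conventional 3 Gy."""

    alpha_beta: float = 3.0

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha_beta must be > 0, got {self.alpha_beta}")


class DVH:
    """Differential dose-volume histogram with absolute bin volumes (cm^3).

    Bins are point masses at strictly increasing representative doses. The
    dose axis is tagged ``physical`` or ``bed``; metric extraction on the BED
    axis goes through :func:`bed_transform_dvh`.
    """

    __slots__ = ("bin_dose", "bin_volume", "dose_kind")

    def __init__(self, bin_dose, bin_volume, dose_kind: str = "physical") -> None:
        bin_dose = np.asarray(bin_dose, dtype=float)
        bin_volume = np.asarray(bin_volume, dtype=float)
        if bin_dose.ndim != 1 or bin_dose.shape != bin_volume.shape:
            raise ValueError("bin_dose and bin_volume must be 1-D arrays of equal length")
        if bin_dose.size == 0:
            raise ValueError("DVH must have at least one bin")
        if np.any(np.diff(bin_dose) <= 0):
            raise ValueError("bin_dose must be strictly increasing")
        if np.any(bin_dose < 0):
            raise ValueError("bin doses must be non-negative")
        if np.any(bin_volume < 0):
            raise ValueError("bin volumes must be non-negative")
        if dose_kind not in ("physical", "bed"):
            raise ValueError(f"dose_kind must be 'physical' or 'bed', got {dose_kind!r}")
        self.bin_dose = bin_dose
        self.bin_volume = bin_volume
        self.dose_kind = dose_kind

    @property
    def total_volume(self) -> float:
        return float(self.bin_volume.sum())

    @property
    def max_dose(self) -> float:
        return float(self.bin_dose[-1])

    @property
    def min_dose(self) -> float:
        return float(self.bin_dose[0])

    @property
    def mean_dose(self) -> float:
        tv = self.total_volume
        if tv <= 0:
            raise ValueError("mean dose undefined for zero total volume")
        return float(np.dot(self.bin_dose, self.bin_volume) / tv)

    def cumulative(self) -> tuple[np.ndarray, np.ndarray]:
        """Cumulative curve: (dose, absolute volume receiving >= dose)."""
        cum = np.cumsum(self.bin_volume[::-1])[::-1]
        return self.bin_dose.copy(), cum

    @classmethod
    def from_cumulative(cls, dose, cum_volume, dose_kind: str = "physical") -> "DVH":
        """Build from cumulative points (dose, volume receiving >= dose)."""
        dose = np.asarray(dose, dtype=float)
        cum = np.asarray(cum_volume, dtype=float)
        if np.any(np.diff(dose) <= 0):
            raise ValueError("cumulative dose axis must be strictly increasing")
        if np.any(np.diff(cum) > 0):
            raise ValueError("cumulative volumes must be non-increasing")
        diff = np.empty_like(cum)
        diff[:-1] = cum[:-1] - cum[1:]
        diff[-1] = cum[-1]
        return cls(dose, diff, dose_kind=dose_kind)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DVH):
            return NotImplemented
        return (
            self.dose_kind == other.dose_kind
            and np.array_equal(self.bin_dose, other.bin_dose)
            and np.array_equal(self.bin_volume, other.bin_volume)
        )

    def __repr__(self) -> str:
        return (
            f"DVH({self.bin_dose.size} bins, {self.dose_kind}, "
            f"total={self.total_volume:.2f} cm3, max={self.max_dose:.2f} Gy)"
        )


@dataclass(frozen=True)
class DoseMetricSpec:
    """A candidate dosimetric predictor evaluated on the BED dose axis.

    kind:
        ``"EUD"`` with ``parameter`` = volume exponent n in (0, 1];
        ``"V_D"`` with ``parameter`` = BED threshold (Gy);
        ``"D_xcm3"`` with ``parameter`` = hottest volume x (cm^3).
    """

    kind: str
    parameter: float

    def __post_init__(self) -> None:
        if self.kind not in ("EUD", "V_D", "D_xcm3"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind == "EUD" and not (0 < self.parameter <= 1):
            raise ValueError(f"EUD volume exponent must be in (0, 1], got {self.parameter}")
        if self.kind in ("V_D", "D_xcm3") and self.parameter <= 0:
            raise ValueError(f"{self.kind} parameter must be > 0, got {self.parameter}")

    @property
    def label(self) -> str:
        if self.kind == "EUD":
            return f"EUD(n={self.parameter:g})"
        if self.kind == "V_D":
            return f"V{self.parameter:.1f}"
        return f"D_{self.parameter:g}cm3"

    @property
    def units(self) -> str:
        return "%" if self.kind == "V_D" else "Gy"


def physical_to_bed(
    total_dose, scheme: FractionationScheme, rb: RadiobiologyParams
):
    """Convert total physical dose (Gy) to BED (Gy) under a schedule.

    The voxel receives ``total_dose / N`` per fraction, so
    ``BED = D * (1 + (D/N) / (alpha/beta))``.  Accepts scalars or arrays;
    strictly increasing in D and always >= D.
    """
    d = np.asarray(total_dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("total_dose must be non-negative")
    bed = d * (1.0 + (d / scheme.n_fractions) / rb.alpha_beta)
    if np.isscalar(total_dose) or np.ndim(total_dose) == 0:
        return float(bed)
    return bed


def bed_transform_dvh(dvh: DVH, scheme: FractionationScheme, rb: RadiobiologyParams) -> DVH:
    """Map a physical-dose DVH onto the BED axis, volumes untouched.

    BED is strictly monotone in dose for fixed (N, alpha/beta), so bin
    membership is preserved and only the dose axis changes.
    """
    if dvh.dose_kind != "physical":
        raise ValueError("bed_transform_dvh expects a physical-dose DVH")
    return DVH(physical_to_bed(dvh.bin_dose, scheme, rb), dvh.bin_volume.copy(), dose_kind="bed")


def eud(dvh: DVH, n: float) -> float:
    """Generalized equivalent uniform dose ``(sum_i v_i D_i^{1/n})^n``.

    ``n`` is the volume exponent (Niemierko/Lyman convention, a = 1/n);
    n = 1 gives the mean dose, n -> 0 the maximum dose.  Evaluated in log
    space so small n (large a) cannot overflow.
    """
    if not (0 < n <= 1):
        raise ValueError(f"volume exponent n must be in (0, 1], got {n}")
    tv = dvh.total_volume
    if tv <= 0:
        raise ValueError("EUD undefined for zero total volume")
    mask = dvh.bin_volume > 0
    dose = dvh.bin_dose[mask]
    vol = dvh.bin_volume[mask]
    if np.all(dose == 0):
        return 0.0
    a = 1.0 / n
    with np.errstate(divide="ignore"):
        log_terms = np.log(vol / tv) + a * np.log(dose)
    return float(np.exp(n * logsumexp(log_terms)))


def v_d(dvh: DVH, threshold: float) -> float:
    """Percent of organ volume receiving at least ``threshold`` Gy (inclusive)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    tv = dvh.total_volume
    if tv <= 0:
        raise ValueError("V_D undefined for zero total volume")
    return float(100.0 * dvh.bin_volume[dvh.bin_dose >= threshold].sum() / tv)


def d_xcm3(dvh: DVH, x: float) -> float:
    """Minimum dose (Gy) within the hottest ``x`` cm^3 of the organ.

    Solves V(D) = x on the cumulative absolute-volume curve by linear
    interpolation between adjacent cumulative points; x above the hottest
    bin's volume but within the organ interpolates, x at total volume
    returns the minimum bin dose.
    """
    tv = dvh.total_volume
    if tv <= 0:
        raise ValueError("D_xcm3 undefined for zero total volume")
    if not (0 < x <= tv):
        raise ValueError(
            f"hottest-volume x={x} cm3 exceeds the organ volume {tv:.3f} cm3 (or is <= 0)"
        )
    dose, cum = dvh.cumulative()
    if x <= cum[-1]:  # inside (or hotter than) the hottest bin
        return float(dose[-1])
    # cum is decreasing in dose; np.interp needs ascending x-coordinates
    return float(np.interp(x, cum[::-1], dose[::-1]))


def compute_metric(
    dvh: DVH,
    spec: DoseMetricSpec,
    scheme: FractionationScheme,
    rb: RadiobiologyParams,
) -> float:
    """BED-transform a physical DVH and evaluate one dose metric on it."""
    if dvh.dose_kind != "physical":
        raise ValueError("compute_metric expects a physical-dose DVH")
    bed = bed_transform_dvh(dvh, scheme, rb)
    if spec.kind == "EUD":
        return eud(bed, spec.parameter)
    if spec.kind == "V_D":
        return v_d(bed, spec.parameter)
    return d_xcm3(bed, spec.parameter)


def alpha_beta_crossover(
    scheme_a: FractionationScheme, scheme_b: FractionationScheme
) -> float | None:
    """alpha/beta (Gy) at which the two prescription BEDs coincide.

    Setting ``D_a (1 + d_a/x) = D_b (1 + d_b/x)`` gives
    ``x = (D_a d_a - D_b d_b) / (D_b - D_a)``.  Returns None when no
    positive solution exists (e.g. equal total doses with different
    fraction sizes); identical schemes are rejected.
    """
    da, db = scheme_a.dose_per_fraction, scheme_b.dose_per_fraction
    Da, Db = scheme_a.prescribed_dose, scheme_b.prescribed_dose
    if Da == Db and da == db:
        raise ValueError("crossover undefined for identical schemes")
    denom = Db - Da
    if denom == 0:
        return None
    x = (Da * da - Db * db) / denom
    return x if x > 0 else None


# ---------------------------------------------------------------------------
# CSV I/O: `dose_gy,volume_cm3` (differential) or `dose_gy,cum_volume_cm3`
# (cumulative), selected by a `# dvh_kind:` metadata line.

def read_dvh_csv(path: Union[str, Path, io.TextIOBase]) -> DVH:
    """Read a physical-dose DVH CSV; differential or cumulative flavor."""
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    kind = "differential"
    for line in text.splitlines():
        if line.startswith("#") and "dvh_kind:" in line:
            kind = line.split("dvh_kind:", 1)[1].strip()
        elif not line.startswith("#"):
            break
    if kind not in ("differential", "cumulative"):
        raise ValueError(f"unknown dvh_kind {kind!r}")
    df = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
    if kind == "cumulative":
        if "cum_volume_cm3" not in df.columns:
            raise ValueError("cumulative DVH CSV requires a 'cum_volume_cm3' column")
        return DVH.from_cumulative(df["dose_gy"].to_numpy(), df["cum_volume_cm3"].to_numpy())
    if "volume_cm3" not in df.columns:
        raise ValueError("differential DVH CSV requires a 'volume_cm3' column")
    return DVH(df["dose_gy"].to_numpy(), df["volume_cm3"].to_numpy())


def write_dvh_csv(dvh: DVH, path: Union[str, Path]) -> None:
    """Write a physical-dose DVH as a differential CSV (full float precision)."""
    if dvh.dose_kind != "physical":
        raise ValueError("DVH files store physical dose; transform before analysis, not I/O")
    with open(path, "w") as fh:
        fh.write("# dvh_kind: differential\n")
        fh.write("dose_gy,volume_cm3\n")
        for d, v in zip(dvh.bin_dose, dvh.bin_volume):
            fh.write(f"{float(d)!r},{float(v)!r}\n")
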