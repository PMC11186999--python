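"""Species records and derived sperm-head / karyotype quantities.

Raw inputs per species: sperm head length l and (for spatulate heads) width w
in micrometres, the measurement method (optical vs. scanning/transmission
electron microscopy), the clade and head-shape class, the haploid autosome
complement (count n, longest and shortest autosome lengths), and the haploid
genome size C in picograms.

Derived quantities:

* EM-corrected dimensions — electron-microscopy measurements systematically
  understate head size by about a micrometre, so a fixed offset (default
  1.0 um) is added to all SEM/TEM head lengths and to mammal widths.
* projected head area A = (pi/4) l w (exact for an ellipse, and for an
  ellipse cut in half across its minor axis);
* chromosome dispersity K = L_max / L_min over autosomes only — invariant to
  mitotic contraction because relative chromosome lengths are conserved;
* genome-normalized dimensions A/C and l/C, which proxy the degree of
  nuclear flattening/elongation per unit DNA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidKaryotypeError, InvalidMeasurementError

logger = logging.getLogger("karyomorph.traits")

#: Autosomes shorter than this (um) are flagged as imprecisely measurable.
LMIN_PRECISION_FLOOR_UM = 0.5


class Clade(str, Enum):
    MAMMAL = "mammal"
    SAUROPSID = "sauropsid"


class HeadShape(str, Enum):
    SPATULATE = "spatulate"
    VERMIFORM = "vermiform"


class Method(str, Enum):
    OPTICAL = "optical"
    SEM = "SEM"
    TEM = "TEM"


class Cohort(str, Enum):
    SPATULATE_MAMMAL = "spatulate_mammal"
    VERMIFORM_SAUROPSID = "vermiform_sauropsid"

    @property
    def clade(self) -> Clade:
        return Clade.MAMMAL if self is Cohort.SPATULATE_MAMMAL else Clade.SAUROPSID

    @property
    def head_shape(self) -> HeadShape:
        return (HeadShape.SPATULATE if self is Cohort.SPATULATE_MAMMAL
                else HeadShape.VERMIFORM)


@dataclass
class KaryotypeSummary:
    """Haploid autosome count plus longest/shortest autosome lengths."""

    haploid_n: int
    L_max_um: float | None = None
    L_min_um: float | None = None

    def __post_init__(self) -> None:
        if self.haploid_n < 1:
            raise InvalidKaryotypeError(f"haploid n must be >= 1, got {self.haploid_n}")
        if (self.L_max_um is None) != (self.L_min_um is None):
            raise InvalidKaryotypeError("L_max and L_min must be given together")
        if self.L_min_um is not None:
            if self.L_min_um <= 0 or self.L_max_um < self.L_min_um:
                raise InvalidKaryotypeError(
                    f"need L_max >= L_min > 0, got ({self.L_max_um}, {self.L_min_um})")
            if self.L_min_um < LMIN_PRECISION_FLOOR_UM:
                logger.debug("L_min = %.3g um is below the ~%.1f um precision floor",
                             self.L_min_um, LMIN_PRECISION_FLOOR_UM)

    @property
    def dispersity(self) -> float | None:
        """K = L_max / L_min, or None when lengths are unavailable."""
        if self.L_min_um is None:
            return None
        return self.L_max_um / self.L_min_um


@dataclass
class SpeciesRecord:
    species_name: str
    clade: Clade
    head_shape: HeadShape
    head_length_um: float
    method: Method
    karyotype: KaryotypeSummary
    head_width_um: float | None = None
    nucleus_fraction: float | None = None
    genome_pg: float | None = None

    def __post_init__(self) -> None:
        self.clade = Clade(self.clade)
        self.head_shape = HeadShape(self.head_shape)
        self.method = Method(self.method)
        if self.head_length_um <= 0:
            raise InvalidMeasurementError(
                f"{self.species_name}: head length must be > 0")
        if self.head_width_um is not None and self.head_width_um <= 0:
            raise InvalidMeasurementError(
                f"{self.species_name}: head width must be > 0")
        if self.head_shape is HeadShape.SPATULATE and self.head_width_um is None:
            raise InvalidMeasurementError(
                f"{self.species_name}: spatulate heads require a width")
        if self.genome_pg is not None and self.genome_pg <= 0:
            raise InvalidMeasurementError(
                f"{self.species_name}: genome size must be > 0")
        if self.nucleus_fraction is not None and not 0 < self.nucleus_fraction <= 1:
            raise InvalidMeasurementError(
                f"{self.species_name}: nucleus fraction must be in (0, 1]")


@dataclass
class HeadMetrics:
    """EM-corrected dimensions plus area and genome-normalized quantities."""

    length_corrected_um: float
    width_corrected_um: float | None
    area_um2: float | None
    area_per_pg: float | None
    length_per_pg: float | None


def apply_em_correction(length_um: float, width_um: float | None, method: Method,
                        clade: Clade, magnitude: float = 1.0,
                        ) -> tuple[float, float | None]:
    """Correct electron-microscopy shrinkage of head dimensions.

    SEM/TEM measurements receive ``magnitude`` (um, default 1.0) added to the
    head length, and to the width for mammals only; optical measurements are
    returned unchanged.
    """
    if length_um <= 0:
        raise InvalidMeasurementError(f"head length must be > 0, got {length_um}")
    if magnitude < 0:
        raise InvalidMeasurementError(f"correction magnitude must be >= 0")
    method = Method(method)
    clade = Clade(clade)
    if method is Method.OPTICAL:
        return length_um, width_um
    length = length_um + magnitude
    width = width_um
    if width is not None and clade is Clade.MAMMAL:
        width = width + magnitude
    return length, width


def head_area(length_um: float, width_um: float) -> float:
    """Projected head area A = (pi/4) l w in um^2."""
    if length_um <= 0 or width_um <= 0:
        raise InvalidMeasurementError("head dimensions must be > 0")
    return math.pi / 4.0 * length_um * width_um


def dispersity(autosome_lengths_um: Sequence[float]) -> float:
    """Chromosome dispersity K = L_max / L_min of an autosome length list.

    Sex chromosomes and supernumerary B chromosomes must already be excluded.
    """
    if len(autosome_lengths_um) == 0:
        raise InvalidKaryotypeError("autosome length list is empty")
    lengths = np.asarray(autosome_lengths_um, dtype=float)
    if np.any(lengths <= 0):
        raise InvalidKaryotypeError("autosome lengths must all be > 0")
    lmin = float(lengths.min())
    if lmin < LMIN_PRECISION_FLOOR_UM:
        logger.debug("shortest autosome %.3g um is below the ~%.1f um precision floor",
                     lmin, LMIN_PRECISION_FLOOR_UM)
    return float(lengths.max()) / lmin


def normalize_by_genome(dimension: float, genome_pg: float | None) -> float | None:
    """Dimension divided by genome size (um^2/pg or um/pg); None when C missing."""
    if genome_pg is None:
        return None
    if dimension <= 0 or genome_pg <= 0:
        raise InvalidMeasurementError("dimension and genome size must be > 0")
    return dimension / genome_pg


def derive_head_metrics(record: SpeciesRecord, correction_um: float = 1.0) -> HeadMetrics:
    """EM-correct dimensions, then derive area and genome-normalized quantities.

    Corrections are applied to l and w before computing A, because A is
    defined from the corrected dimensions. Vermiform analyses use length only;
    a width, if present, is carried but unused downstream.
    """
    length, width = apply_em_correction(record.head_length_um, record.head_width_um,
                                        record.method, record.clade, correction_um)
    area = head_area(length, width) if width is not None else None
    area_per_pg = (normalize_by_genome(area, record.genome_pg)
                   if area is not None else None)
    length_per_pg = normalize_by_genome(length, record.genome_pg)
    return HeadMetrics(length, width, area, area_per_pg, length_per_pg)


def filter_cohort(records: Iterable[SpeciesRecord], cohort: Cohort,
                  require_genome: bool = False) -> list[SpeciesRecord]:
    """Select one cohort's records, applying the nucleus-occupancy screen.

    Retains records whose clade and head shape match the cohort and whose
    nucleus occupies at least 50% of head length when that fraction is known
    (records without the datum are presumed pre-screened). With
    ``require_genome`` set, records lacking a genome size are also excluded.
    Every exclusion is logged with its reason.
    """
    cohort = Cohort(cohort)
    out: list[SpeciesRecord] = []
    for rec in records:
        if rec.clade is not cohort.clade or rec.head_shape is not cohort.head_shape:
            logger.info("%s excluded: not in cohort %s", rec.species_name, cohort.value)
            continue
        if rec.nucleus_fraction is not None and rec.nucleus_fraction < 0.5:
            logger.info("%s excluded: nucleus fraction %.2f < 0.5",
                        rec.species_name, rec.nucleus_fraction)
            continue
        if require_genome and rec.genome_pg is None:
            logger.info("%s excluded: genome size missing", rec.species_name)
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Species-table I/O and the derived trait frame

TABLE_COLUMNS = ["species", "clade", "head_shape", "head_length_um", "head_width_um",
                 "method", "nucleus_fraction", "haploid_n", "L_max_um", "L_min_um",
                 "genome_pg", "source"]


def _opt(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_species_table(path: str, delimiter: str = ",") -> list[SpeciesRecord]:
    """Read the delimited species table (one header row; empty field = missing)."""
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns and c != "source"]
    if missing:
        raise InvalidMeasurementError(f"species table lacks columns: {missing}")
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[SpeciesRecord]:
    records = []
    for row in df.itertuples(index=False):
        kar = KaryotypeSummary(haploid_n=int(row.haploid_n),
                               L_max_um=_opt(row.L_max_um),
                               L_min_um=_opt(row.L_min_um))
        records.append(SpeciesRecord(
            species_name=str(row.species),
            clade=Clade(row.clade),
            head_shape=HeadShape(row.head_shape),
            head_length_um=float(row.head_length_um),
            head_width_um=_opt(row.head_width_um),
            method=Method(row.method),
            nucleus_fraction=_opt(row.nucleus_fraction),
            genome_pg=_opt(row.genome_pg),
            karyotype=kar))
    low = sum(1 for r in records
              if r.karyotype.L_min_um is not None
              and r.karyotype.L_min_um < LMIN_PRECISION_FLOOR_UM)
    if low:
        logger.warning("%d of %d species have L_min below the ~%.1f um precision "
                       "floor; dispersity values for these are imprecise",
                       low, len(records), LMIN_PRECISION_FLOOR_UM)
    return records


def build_trait_frame(records: Iterable[SpeciesRecord],
                      correction_um: float = 1.0) -> pd.DataFrame:
    """Analysis-ready table: one row per species, log10 trait columns.

    Columns: species, cohort, s (0 spatulate mammal / 1 vermiform sauropsid),
    log10_n, log10_K, log10_Lmin, log10_C, log10_area, log10_length,
    log10_area_per_pg, log10_length_per_pg; NaN marks a missing value.
    """
    rows = []
    for rec in records:
        m = derive_head_metrics(rec, correction_um)
        K = rec.karyotype.dispersity
        lg = lambda v: math.log10(v) if v is not None else math.nan
        rows.append({
            "species": rec.species_name,
            "cohort": (Cohort.SPATULATE_MAMMAL.value
                       if rec.head_shape is HeadShape.SPATULATE
                       else Cohort.VERMIFORM_SAUROPSID.value),
            "s": 0.0 if rec.head_shape is HeadShape.SPATULATE else 1.0,
            "log10_n": lg(rec.karyotype.haploid_n),
            "log10_K": lg(K),
            "log10_Lmin": lg(rec.karyotype.L_min_um),
            "log10_C": lg(rec.genome_pg),
            "log10_area": lg(m.area_um2),
            "log10_length": lg(m.length_corrected_um),
            "log10_area_per_pg": lg(m.area_per_pg),
            "log10_length_per_pg": lg(m.length_per_pg),
        })
    return pd.DataFrame(rows)
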