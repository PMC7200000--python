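"""Genotype data model, readers/writers, and locus filters.

The shared substrate for every genetic analysis in this package is a
diploid dosage matrix: individuals x biallelic loci, with each cell
counting copies of the alternate allele (0, 1, 2) or ``MISSING``.
Individuals carry a population (site) label and an optional
sampling-period label so that temporal panels can live in one matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing genotype call.
MISSING: int = -1

_VALID_REGIONS = ("northern", "southern")


class GenotypeValidationError(ValueError):
    """Raised when genotype input violates the data model."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP genotypes for a set of individuals.

    Parameters
    ----------
    sample_ids
        Unique individual identifiers, one per matrix row.
    locus_ids
        Unique locus identifiers, one per matrix column.
    dosages
        ``(n_individuals, n_loci)`` integer array of alternate-allele
        counts in ``{0, 1, 2, MISSING}``.
    population
        Per-individual site label.
    period
        Per-individual sampling-period label (e.g. ``"2016-2018"``).
        Defaults to a single unnamed period.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosages: np.ndarray
    population: np.ndarray
    period: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.population = np.asarray(self.population, dtype=object)
        if self.period is None:
            self.period = np.asarray([""] * len(self.sample_ids), dtype=object)
        else:
            self.period = np.asarray(self.period, dtype=object)
        self.validate()

    # -- basic protocol ------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    def validate(self) -> None:
        n, L = self.dosages.shape
        if len(self.sample_ids) != n:
            raise GenotypeValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.locus_ids) != L:
            raise GenotypeValidationError(
                f"{len(self.locus_ids)} locus ids for {L} columns"
            )
        if len(set(self.locus_ids)) != L:
            raise GenotypeValidationError("locus ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise GenotypeValidationError("sample ids are not unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeValidationError(
                f"invalid dosage {self.dosages[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        if self.population.shape != (n,) or any(not p for p in self.population):
            raise GenotypeValidationError("population labels missing or wrong length")
        if self.period.shape != (n,):
            raise GenotypeValidationError("period labels wrong length")

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(pd.unique(self.population))

    def pop_mask(self, population: str) -> np.ndarray:
        mask = self.population == population
        if not mask.any():
            raise GenotypeValidationError(f"unknown population {population!r}")
        return mask

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            locus_ids=[self.locus_ids[i] for i in index],
            dosages=self.dosages[:, index],
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in index],
            dosages=self.dosages[index],
            population=self.population[index],
            period=self.period[index],
        )

    def subset(self, population: str, period: str | None = None) -> "GenotypeMatrix":
        """Individuals of one population (optionally one period)."""
        mask = self.pop_mask(population)
        if period is not None:
            mask = mask & (self.period == period)
            if not mask.any():
                raise GenotypeValidationError(
                    f"no individuals in {population!r} / period {period!r}"
                )
        return self.take_individuals(np.flatnonzero(mask))

    def allele_frequencies(self, population: str | None = None) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing gene copies.

        NaN where a locus has no calls in the chosen scope.
        """
        d = self.dosages if population is None else self.dosages[self.pop_mask(population)]
        called = d != MISSING
        copies = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)


def concat_individuals(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices that share the same locus set."""
    if a.locus_ids != b.locus_ids:
        raise GenotypeValidationError("matrices must share identical loci")
    return GenotypeMatrix(
        sample_ids=a.sample_ids + b.sample_ids,
        locus_ids=a.locus_ids,
        dosages=np.vstack([a.dosages, b.dosages]),
        population=np.concatenate([a.population, b.population]),
        period=np.concatenate([a.period, b.period]),
    )


@dataclass
class SiteMetadata:
    """Per-site attributes used by distance, Ne/Na and rescue analyses."""

    site: str
    region: str
    longitude: float
    latitude: float
    isolated: bool = False
    modal_na: int | None = None
    nearest_neighbor: str | None = None

    def __post_init__(self) -> None:
        if self.region not in _VALID_REGIONS:
            raise GenotypeValidationError(
                f"region must be one of {_VALID_REGIONS}, got {self.region!r}"
            )
        if not (np.isfinite(self.longitude) and np.isfinite(self.latitude)):
            raise GenotypeValidationError(f"non-finite coordinates for {self.site!r}")


def read_site_metadata(path) -> list[SiteMetadata]:
    """Read a site-metadata CSV (site, region, longitude, latitude, isolated, modal_na)."""
    df = pd.read_csv(path, comment="#")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SiteMetadata(
                site=str(row.site),
                region=str(row.region),
                longitude=float(row.longitude),
                latitude=float(row.latitude),
                isolated=bool(getattr(row, "isolated", False)),
                modal_na=None
                if pd.isna(getattr(row, "modal_na", np.nan))
                else int(row.modal_na),
                nearest_neighbor=getattr(row, "nearest_neighbor", None),
            )
        )
    return out


# ---------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------

def read_vcf(
    path,
    population_map: dict[str, str] | None = None,
    period_map: dict[str, str] | None = None,
    multiallelic: str = "skip",
) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF into a dosage matrix.

    Parameters
    ----------
    path
        Path to an (uncompressed or bgzipped) VCF file.
    population_map, period_map
        Optional sample -> label mappings; samples absent from
        ``population_map`` get population ``"pop"``.
    multiallelic
        ``"skip"`` drops records with more than one ALT allele (with a
        logged warning); ``"error"`` raises.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise GenotypeValidationError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    locus_ids: list[str] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            if multiallelic == "skip":
                n_skipped += 1
                continue
            raise GenotypeValidationError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS}"
            )
        dos = np.empty(len(samples), dtype=np.int16)
        for i, call in enumerate(variant.genotypes):
            alleles = call[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise GenotypeValidationError(
                    f"non-diploid call for sample {samples[i]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                dos[i] = MISSING
            else:
                dos[i] = alleles[0] + alleles[1]
        vid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        locus_ids.append(vid)
        rows.append(dos)
    if n_skipped:
        logger.warning("skipped %d multi-allelic VCF records", n_skipped)
    dosages = (
        np.array(rows, dtype=np.int16).T
        if rows
        else np.empty((len(samples), 0), dtype=np.int16)
    )
    population = [
        (population_map or {}).get(s, "pop") for s in samples
    ]
    period = [(period_map or {}).get(s, "") for s in samples]
    return GenotypeMatrix(samples, locus_ids, dosages, population, period)


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read the package's TSV genotype dialect.

    Columns: ``sample_id``, ``population``, ``period``, then one column
    per locus holding 0/1/2 or ``NA``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    fixed = ["sample_id", "population", "period"]
    for col in fixed:
        if col not in df.columns:
            raise GenotypeValidationError(f"TSV missing required column {col!r}")
    locus_ids = [c for c in df.columns if c not in fixed]
    raw = df[locus_ids].to_numpy()
    dosages = np.empty(raw.shape, dtype=np.int16)
    for (i, j), val in np.ndenumerate(raw):
        if val == "NA":
            dosages[i, j] = MISSING
        elif val in ("0", "1", "2"):
            dosages[i, j] = int(val)
        else:
            raise GenotypeValidationError(
                f"invalid dosage {val!r} at row {i + 1}, column {locus_ids[j]!r}"
            )
    return GenotypeMatrix(
        list(df["sample_id"]), locus_ids, dosages,
        df["population"].to_numpy(), df["period"].to_numpy(),
    )


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    """Write the TSV dialect read by :func:`read_genotype_tsv` (bit-exact round trip)."""
    cells = np.where(g.dosages == MISSING, "NA", g.dosages.astype(str))
    df = pd.DataFrame(cells, columns=g.locus_ids)
    df.insert(0, "period", g.period)
    df.insert(0, "population", g.population)
    df.insert(0, "sample_id", g.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def write_genepop(g: GenotypeMatrix, path, title: str = "gartergen export") -> None:
    """Write a two-digit genepop file (allele 01 = reference, 02 = alternate)."""
    code = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write("\n".join(g.locus_ids) + "\n")
        for pop in g.populations():
            fh.write("POP\n")
            sub = g.subset(pop)
            for i, sid in enumerate(sub.sample_ids):
                geno = " ".join(code[int(d)] for d in sub.dosages[i])
                fh.write(f"{pop}_{sid} ,  {geno}\n")


# ---------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------

def filter_by_presence(
    g: GenotypeMatrix, min_fraction: float, per_population: bool = True
) -> GenotypeMatrix:
    """Keep loci genotyped in at least ``min_fraction`` of individuals.

    With ``per_population=True`` (the default) the threshold must hold
    within *every* population; this is the panel-construction filter
    used to retain loci present across all sampled sites in at least a
    given share of individuals. Boundary inclusive: a locus typed in
    exactly ``min_fraction`` of individuals is retained. Idempotent.
    """
    if not (0 < min_fraction <= 1):
        raise GenotypeValidationError("min_fraction must be in (0, 1]")
    called = g.dosages != MISSING
    if per_population:
        keep = np.ones(g.n_loci, dtype=bool)
        for pop in g.populations():
            mask = g.pop_mask(pop)
            n = int(mask.sum())
            if n == 0:
                raise GenotypeValidationError(f"population {pop!r} has no individuals")
            frac = called[mask].sum(axis=0) / n
            # small epsilon so exact-boundary fractions survive float division
            keep &= frac >= min_fraction - 1e-12
    else:
        keep = called.sum(axis=0) / g.n_individuals >= min_fraction - 1e-12
    return g.take_loci(np.flatnonzero(keep))


def screen_maf(
    g: GenotypeMatrix,
    pcrit: float,
    scope: str = "pooled",
    drop_fixed: bool = True,
) -> GenotypeMatrix:
    """Remove loci whose minor-allele frequency is below ``pcrit``.

    Mirrors the rare-allele screen applied before Ne estimation: a
    frequency exactly equal to ``pcrit`` is *retained* (alleles with
    frequency strictly below the critical value are excluded).

    ``scope="population"`` removes a locus if its MAF falls below
    ``pcrit`` in any population; ``"pooled"`` uses the pooled frequency.
    With ``pcrit=0`` only fixed loci are dropped (or nothing, when
    ``drop_fixed`` is false).
    """
    if not (0 <= pcrit < 0.5):
        raise GenotypeValidationError("pcrit must be in [0, 0.5)")
    if scope not in ("population", "pooled"):
        raise GenotypeValidationError(f"unknown scope {scope!r}")

    def maf(pop: str | None) -> np.ndarray:
        p = g.allele_frequencies(pop)
        return np.minimum(p, 1 - p)

    def keep_at(m: np.ndarray) -> np.ndarray:
        if pcrit == 0:
            return (m > 0) if drop_fixed else ~np.isnan(m)
        return m >= pcrit - 1e-12

    if scope == "pooled":
        keep = keep_at(maf(None))
    else:
        keep = np.ones(g.n_loci, dtype=bool)
        for pop in g.populations():
            keep &= keep_at(maf(pop))
    keep &= ~np.isnan(maf(None))
    return g.take_loci(np.flatnonzero(keep))
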