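"""Tabular I/O and domain containers for multi-family DH QTL mapping.

All files are comma-separated UTF-8 with a header row; missing values are
spelled ``NA``.  Genetic-map positions are in centimorgans (cM), 0-based at
the start of each chromosome.  Chromosome names encode the subgenome by
their trailing letter (``5A``, ``1B``, ``5R`` for the wheat A/B and rye R
genomes of hexaploid triticale).  Doubled-haploid (DH) genotypes are coded
as the number of copies of the family's reference-parent allele, which for
fully homozygous DH lines is 0 or 2.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

GENOMES = ("A", "B", "R")
NA = "NA"


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def genome_of(chromosome: str) -> str:
    """Subgenome letter of a chromosome name (last character)."""
    g = str(chromosome)[-1]
    if g not in GENOMES:
        raise FormatError(
            f"cannot parse genome from chromosome name {chromosome!r}; "
            f"expected trailing letter in {GENOMES}"
        )
    return g


def _chrom_sort_key(name: str):
    # "5A" -> (genome index, numeric prefix); falls back to lexicographic.
    g = genome_of(name)
    num = name[:-1]
    try:
        n = int(num)
    except ValueError:
        n = 10**6
    return (GENOMES.index(g), n, name)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered markers with cM positions on genome-labelled chromosomes.

    ``markers`` has columns ``marker_id``, ``chromosome``, ``position_cM``
    and is sorted by (chromosome, position).
    """

    markers: pd.DataFrame

    def __post_init__(self):
        df = self.markers
        required = {"marker_id", "chromosome", "position_cM"}
        if not required.issubset(df.columns):
            raise FormatError(f"map requires columns {sorted(required)}")
        if df["marker_id"].duplicated().any():
            dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise FormatError(f"duplicate marker_id {dup!r}")
        if (df["position_cM"] < 0).any():
            raise FormatError("marker positions must be >= 0 cM")
        for c in df["chromosome"].unique():
            genome_of(c)  # raises on unparsable names
        counts = df["chromosome"].value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index[0]
            raise FormatError(f"chromosome {bad!r} has fewer than 2 markers")
        df = df.sort_values(
            by=["chromosome", "position_cM"],
            key=lambda s: s.map(_chrom_sort_key) if s.name == "chromosome" else s,
            kind="stable",
        ).reset_index(drop=True)
        object.__setattr__(self, "markers", df)

    @property
    def chromosomes(self) -> list[tuple[str, str]]:
        """Ordered (name, genome) pairs."""
        names = list(dict.fromkeys(self.markers["chromosome"]))
        return [(c, genome_of(c)) for c in names]

    @property
    def chromosome_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["marker_id"].tolist()

    def chrom_markers(self, chromosome: str) -> pd.DataFrame:
        sub = self.markers[self.markers["chromosome"] == chromosome]
        if sub.empty:
            raise KeyError(f"no such chromosome {chromosome!r}")
        return sub

    def chrom_positions(self, chromosome: str) -> np.ndarray:
        return self.chrom_markers(chromosome)["position_cM"].to_numpy(float)

    def chrom_length(self, chromosome: str) -> float:
        return float(self.chrom_positions(chromosome)[-1])

    def marker_position(self, marker_id: str) -> tuple[str, float]:
        row = self.markers[self.markers["marker_id"] == marker_id]
        if row.empty:
            raise KeyError(f"no such marker {marker_id!r}")
        r = row.iloc[0]
        return str(r["chromosome"]), float(r["position_cM"])


@dataclass(frozen=True)
class FamilyStructure:
    """Family membership of the DH lines.

    ``families``: columns ``family_id``, ``parent1``, ``parent2``, ``n_lines``.
    ``line_to_family``: Series mapping line_id -> family_id.
    """

    families: pd.DataFrame
    line_to_family: pd.Series

    def __post_init__(self):
        fam_ids = set(self.families["family_id"])
        seen = set(self.line_to_family.unique())
        if not seen.issubset(fam_ids):
            raise FormatError(f"lines assigned to unknown families {seen - fam_ids}")
        counts = self.line_to_family.value_counts()
        declared = self.families.set_index("family_id")["n_lines"]
        for f in fam_ids:
            if int(declared.get(f, 0)) != int(counts.get(f, 0)):
                raise FormatError(
                    f"family {f!r}: declared n_lines {declared.get(f)} != "
                    f"observed {counts.get(f, 0)}"
                )

    @property
    def family_ids(self) -> list[str]:
        return self.families["family_id"].tolist()

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_lines(self) -> int:
        return len(self.line_to_family)

    def family_of(self, line_ids) -> np.ndarray:
        return self.line_to_family.loc[list(line_ids)].to_numpy()

    def indicator(self, line_ids) -> np.ndarray:
        """N x P family membership matrix (the J matrix of the joint model)."""
        fams = self.family_ids
        fam = self.family_of(line_ids)
        J = np.zeros((len(fam), len(fams)))
        for p, f in enumerate(fams):
            J[fam == f, p] = 1.0
        return J

    def subset(self, line_ids) -> "FamilyStructure":
        l2f = self.line_to_family.loc[list(line_ids)]
        counts = l2f.value_counts()
        fams = self.families[self.families["family_id"].isin(counts.index)].copy()
        fams["n_lines"] = fams["family_id"].map(counts).astype(int)
        return FamilyStructure(fams.reset_index(drop=True), l2f)


@dataclass(frozen=True)
class MarkerData:
    """Line x marker allele-count matrix (0/2/NaN) with family assignment."""

    line_ids: list[str]
    genotype: np.ndarray  # n x m float; missing = NaN
    family: FamilyStructure
    gmap: GeneticMap

    def __post_init__(self):
        g = np.asarray(self.genotype, float)
        object.__setattr__(self, "genotype", g)
        object.__setattr__(self, "line_ids", list(self.line_ids))
        n, m = g.shape
        if n != len(self.line_ids):
            raise FormatError("genotype rows != number of lines")
        if m != self.gmap.n_markers:
            raise FormatError("genotype columns != number of map markers")
        vals = g[~np.isnan(g)]
        if vals.size and not np.isin(vals, (0.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 2.0))][0]
            raise FormatError(
                f"DH genotype entries must be 0, 2 or missing; found {bad}"
            )
        missing = set(self.line_ids) - set(self.family.line_to_family.index)
        if missing:
            raise FormatError(f"lines absent from family table: {sorted(missing)[:5]}")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def family_indicator(self) -> np.ndarray:
        return self.family.indicator(self.line_ids)

    def family_codes(self) -> np.ndarray:
        """Integer family index per line, in family_ids order."""
        fams = self.family.family_ids
        fam = self.family.family_of(self.line_ids)
        lookup = {f: i for i, f in enumerate(fams)}
        return np.array([lookup[f] for f in fam])

    def subset(self, indices) -> "MarkerData":
        idx = np.asarray(indices)
        lines = [self.line_ids[i] for i in idx]
        return MarkerData(
            line_ids=lines,
            genotype=self.genotype[idx],
            family=self.family.subset(lines),
            gmap=self.gmap,
        )


@dataclass
class RunConfig:
    """Run parameters of the mapping pipeline.

    Defaults follow the study design: genome-wide thresholds from 2000
    permutations at an experiment-wise error rate of 0.10, support intervals
    by a LOD fall-off of 1.0, a 10 cM cofactor-exclusion window, a 10 cM
    overlap window between traits, major-QTL cutoff at 10 % of the genotypic
    variance, and a Bonferroni correction of the epistasis alpha (0.05)
    assuming two independent regions per chromosome.
    """

    scan_step: float = 1.0
    n_permutations: int = 2000
    alpha: float = 0.10
    lod_falloff: float = 1.0
    cofactor_window: float = 10.0
    overlap_window: float = 10.0
    major_pg_cutoff: float = 10.0
    epistasis_alpha: float = 0.05
    regions_per_chromosome: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in (
            "scan_step",
            "n_permutations",
            "lod_falloff",
            "cofactor_window",
            "overlap_window",
            "major_pg_cutoff",
            "regions_per_chromosome",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha", "epistasis_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# readers / writers


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, na_values=[NA])
    return GeneticMap(df[["marker_id", "chromosome", "position_cM"]])


def write_genetic_map(gmap: GeneticMap, path) -> None:
    gmap.markers.to_csv(path, index=False, na_rep=NA)


def read_families(path) -> FamilyStructure:
    df = pd.read_csv(path, na_values=[NA])
    fams = (
        df.groupby("family_id", sort=False)
        .agg(parent1=("parent1", "first"), parent2=("parent2", "first"),
             n_lines=("line_id", "size"))
        .reset_index()
    )
    l2f = df.set_index("line_id")["family_id"].rename(None)
    if l2f.index.duplicated().any():
        raise FormatError("duplicate line_id in family table")
    return FamilyStructure(fams, l2f)


def write_families(fam: FamilyStructure, path) -> None:
    df = fam.line_to_family.rename("family_id").reset_index()
    df.columns = ["line_id", "family_id"]
    meta = fam.families.set_index("family_id")
    df["parent1"] = df["family_id"].map(meta["parent1"])
    df["parent2"] = df["family_id"].map(meta["parent2"])
    df.to_csv(path, index=False, na_rep=NA)


def read_genotypes(path, gmap: GeneticMap, fam: FamilyStructure) -> MarkerData:
    df = pd.read_csv(path, na_values=[NA], dtype={"line_id": str})
    if "line_id" not in df.columns:
        raise FormatError("genotype table requires a line_id column")
    missing_markers = [m for m in gmap.marker_ids if m not in df.columns]
    if missing_markers:
        raise FormatError(f"genotype table lacks markers {missing_markers[:5]}")
    unknown_lines = set(df["line_id"]) - set(fam.line_to_family.index)
    if unknown_lines:
        raise FormatError(f"lines absent from family table: {sorted(unknown_lines)[:5]}")
    geno = df.set_index("line_id")[gmap.marker_ids].to_numpy(float)
    vals = geno[~np.isnan(geno)]
    bad = vals[~np.isin(vals, (0.0, 2.0))]
    if bad.size:
        raise FormatError(
            f"DH genotype entries must be 0, 2 or NA; found {bad[0]}"
        )
    return MarkerData(df["line_id"].tolist(), geno, fam, gmap)


def write_genotypes(geno: MarkerData, path) -> None:
    df = pd.DataFrame(geno.genotype, columns=geno.gmap.marker_ids)
    df.insert(0, "line_id", geno.line_ids)
    df.to_csv(path, index=False, na_rep=NA, float_format="%.0f")


def read_phenotypes(path) -> pd.DataFrame:
    """Plot-level table (line_id, location, replicate, value) or
    pre-adjusted means (line_id, value)."""
    df = pd.read_csv(path, na_values=[NA], dtype={"line_id": str})
    if "line_id" not in df.columns or "value" not in df.columns:
        raise FormatError("phenotype table requires line_id and value columns")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, na_rep=NA)


_QTL_BASE_COLS = ["row_type", "chromosome", "position_cM", "ci_lo_cM", "ci_hi_cM",
                  "lod", "pg"]


def write_qtl_table(qtls, path, family_ids=None) -> None:
    """One row per QTL (chromosome, peak, support interval, overall and
    per-family pG) followed by per-genome summary rows."""
    from .report import genome_summary  # local import: report depends on scan

    if family_ids is None:
        fams: list[str] = []
        for q in qtls:
            for f in q.pg_family:
                if f not in fams:
                    fams.append(f)
    else:
        fams = list(family_ids)
    rows = []
    for q in qtls:
        row = {
            "row_type": "qtl",
            "chromosome": q.chromosome,
            "position_cM": q.position,
            "ci_lo_cM": q.ci_lo,
            "ci_hi_cM": q.ci_hi,
            "lod": q.lod,
            "pg": q.pg_overall,
        }
        for f in fams:
            row[f"pg_{f}"] = q.pg_family.get(f, np.nan)
        rows.append(row)
    summary = genome_summary(qtls)
    for g in GENOMES:
        if g not in summary.index:
            continue
        row = {
            "row_type": "genome_summary",
            "chromosome": g,
            "position_cM": np.nan,
            "ci_lo_cM": np.nan,
            "ci_hi_cM": np.nan,
            "lod": np.nan,
            "pg": summary.loc[g, "pg"],
        }
        for f in fams:
            col = f"pg_{f}"
            row[col] = summary.loc[g, col] if col in summary.columns else np.nan
        rows.append(row)
    cols = _QTL_BASE_COLS + [f"pg_{f}" for f in fams]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, na_rep=NA)


def read_qtl_table(path) -> list:
    """Re-read a QTL table written by :func:`write_qtl_table` (summary rows
    are skipped)."""
    from .scan import QTLRecord

    df = pd.read_csv(path, na_values=[NA])
    fams = [c[3:] for c in df.columns if c.startswith("pg_")]
    out = []
    for _, r in df[df["row_type"] == "qtl"].iterrows():
        pg_family = {}
        for f in fams:
            v = r[f"pg_{f}"]
            if not pd.isna(v):
                pg_family[f] = float(v)
        out.append(
            QTLRecord(
                chromosome=str(r["chromosome"]),
                position=float(r["position_cM"]),
                ci_lo=float(r["ci_lo_cM"]),
                ci_hi=float(r["ci_hi_cM"]),
                lod=float(r["lod"]),
                pg_overall=float(r["pg"]),
                pg_family=pg_family,
            )
        )
    return out
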