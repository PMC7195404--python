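"""Shared data containers and readers for genotype-likelihood data.

Loci follow the VCF convention (1-based positions); feature annotations
follow the BED convention (0-based, half-open). Conversion between the two
happens only inside :func:`near_feature`.

A genotype-likelihood triple that is flat (all three entries equal) encodes
missing data. Missing triples are never dropped; downstream estimators
marginalize over them.
"""

from __future__ import annotations

import enum
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hybridzone")

__all__ = [
    "Role",
    "Sex",
    "LocusMap",
    "PopulationMap",
    "GenotypeLikelihoodMatrix",
    "FeatureTable",
    "RunConfig",
    "read_genotype_likelihoods",
    "read_feature_table",
    "near_feature",
    "write_table",
    "read_table",
]


class Role(str, enum.Enum):
    """Taxon role of a population in the analysis."""

    PARENT0 = "parent0"
    PARENT1 = "parent1"
    HYBRID = "hybrid"
    OTHER = "other"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class LocusMap:
    """Ordered map of biallelic loci.

    Parameters
    ----------
    table
        DataFrame with columns ``locus_id``, ``chromosome``, ``position``
        (1-based bp) and ``is_Z`` (bool). Positions must be strictly
        increasing within each chromosome and locus ids unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"locus_id", "chromosome", "position", "is_Z"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"LocusMap missing columns: {sorted(missing)}")
        if t["locus_id"].duplicated().any():
            dup = t.loc[t["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise ValueError(f"duplicate locus_id: {dup!r}")
        for chrom, grp in t.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy()
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom!r}"
                )
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)

    @property
    def locus_ids(self) -> np.ndarray:
        return self.table["locus_id"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def is_Z(self) -> np.ndarray:
        return self.table["is_Z"].to_numpy(dtype=bool)

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous row ranges per chromosome (loci are stored in order)."""
        out: dict[str, slice] = {}
        chroms = self.table["chromosome"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of individuals to populations and taxon roles."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"individual_id", "population_id", "role"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"PopulationMap missing columns: {sorted(missing)}")
        if t["individual_id"].duplicated().any():
            dup = t.loc[t["individual_id"].duplicated(), "individual_id"].iloc[0]
            raise ValueError(f"duplicate individual_id: {dup!r}")
        t["role"] = t["role"].map(lambda r: Role(r).value)
        if "sex" not in t.columns:
            t["sex"] = Sex.UNKNOWN.value
        else:
            t["sex"] = t["sex"].map(lambda s: Sex(s).value)
        object.__setattr__(self, "table", t.reset_index(drop=True))

    def individuals(
        self,
        population: str | Iterable[str] | None = None,
        role: Role | str | None = None,
        sex: Sex | str | None = None,
    ) -> list[str]:
        t = self.table
        mask = np.ones(len(t), dtype=bool)
        if population is not None:
            pops = [population] if isinstance(population, str) else list(population)
            mask &= t["population_id"].isin(pops).to_numpy()
        if role is not None:
            mask &= (t["role"] == Role(role).value).to_numpy()
        if sex is not None:
            mask &= (t["sex"] == Sex(sex).value).to_numpy()
        return t.loc[mask, "individual_id"].tolist()

    def populations(self, role: Role | str | None = None) -> list[str]:
        t = self.table
        if role is not None:
            t = t[t["role"] == Role(role).value]
        return list(dict.fromkeys(t["population_id"]))

    def population_of(self) -> dict[str, str]:
        return dict(
            zip(self.table["individual_id"], self.table["population_id"])
        )


@dataclass
class GenotypeLikelihoodMatrix:
    """Per-locus, per-individual genotype likelihoods.

    ``gl`` has shape (n_loci, n_individuals, 3): likelihood of carrying 0, 1
    or 2 copies of the counted allele. Triples are normalized to sum to one;
    the model is invariant to per-triple rescaling, so normalization loses
    nothing. A flat triple (1/3, 1/3, 1/3) encodes missing data.
    """

    loci: LocusMap
    individuals: list[str]
    gl: np.ndarray

    def __post_init__(self) -> None:
        gl = np.asarray(self.gl, dtype=float)
        if gl.shape != (len(self.loci), len(self.individuals), 3):
            raise ValueError(
                f"gl shape {gl.shape} does not match "
                f"({len(self.loci)}, {len(self.individuals)}, 3)"
            )
        if np.any(gl < 0):
            raise ValueError("genotype likelihoods must be nonnegative")
        totals = gl.sum(axis=2)
        if np.any(totals <= 0):
            raise ValueError("each GL triple needs a strictly positive entry")
        self.gl = gl / totals[:, :, None]

    @property
    def n_loci(self) -> int:
        return self.gl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gl.shape[1]

    def is_missing(self) -> np.ndarray:
        """Boolean (n_loci, n_ind) mask of flat (uninformative) triples."""
        return np.ptp(self.gl, axis=2) < 1e-12

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeLikelihoodMatrix":
        index = {ind: j for j, ind in enumerate(self.individuals)}
        cols = [index[i] for i in ids]
        return GenotypeLikelihoodMatrix(self.loci, list(ids), self.gl[:, cols, :])

    def subset_loci(self, mask_or_index: np.ndarray) -> "GenotypeLikelihoodMatrix":
        sub = self.loci.table.iloc[
            np.arange(len(self.loci))[mask_or_index]
            if np.asarray(mask_or_index).dtype == bool
            else np.asarray(mask_or_index)
        ]
        return GenotypeLikelihoodMatrix(
            LocusMap(sub), list(self.individuals), self.gl[mask_or_index]
        )


@dataclass(frozen=True)
class FeatureTable:
    """BED-style structural annotations (0-based, half-open)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"chromosome", "start", "end", "feature_class"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"FeatureTable missing columns: {sorted(missing)}")
        bad = t[t["start"] >= t["end"]]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(
                f"feature with start >= end: {r['chromosome']}:{r['start']}-{r['end']}"
            )
        t = t.sort_values(["chromosome", "start"], kind="stable")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def classes(self) -> list[str]:
        return sorted(self.table["feature_class"].unique())


@dataclass
class RunConfig:
    """Seed and per-stage settings shared across the pipeline.

    The contract: identical config plus identical inputs gives identical
    outputs, byte for byte, for every stage.
    """

    seed: int = 0
    out_dir: str = "."
    verbosity: str = "INFO"
    stage_options: dict = field(default_factory=dict)

    def rng(self, stage: str = "") -> np.random.Generator:
        """Stage-scoped generator so stages do not share random streams."""
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _stable_hash(stage)])
        )

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "stage_options": self.stage_options,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


# ---------------------------------------------------------------------------
# Readers


def read_genotype_likelihoods(
    path: str, dialect: str = "beagle_gl"
) -> GenotypeLikelihoodMatrix:
    """Read a genotype-likelihood matrix from text.

    ``beagle_gl``: whitespace-separated table, header
    ``marker allele1 allele2 <ind1> <ind1> <ind1> <ind2> ...`` with three GL
    columns per individual; marker ids of the form ``chrom:pos`` populate the
    locus map (otherwise loci are placed on a single pseudo-chromosome at
    consecutive positions).

    ``vcf_gl``: a VCF with GL (log10-scaled likelihoods) or PL
    (phred-scaled) FORMAT tags; non-biallelic records are skipped and
    counted.
    """
    if dialect == "beagle_gl":
        return _read_beagle(path)
    if dialect == "vcf_gl":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_beagle(path: str) -> GenotypeLikelihoodMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 6 or (len(header) - 3) % 3 != 0:
            raise ValueError(
                f"{path}:1: header must be 'marker allele1 allele2' plus "
                "three columns per individual"
            )
        individuals = list(dict.fromkeys(header[3:]))
        if len(individuals) * 3 != len(header) - 3:
            # header may list each individual once instead of thrice
            if len(header) - 3 == len(header[3:]) and len(header[3:]) % 3 == 0:
                individuals = header[3 : 3 + (len(header) - 3) // 3]
        n_ind = (len(header) - 3) // 3
        individuals = individuals[:n_ind]
        rows, ids = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3 + 3 * n_ind:
                raise ValueError(
                    f"{path}:{lineno}: expected {3 + 3 * n_ind} fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(x) for x in parts[3:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric GL field") from exc
            ids.append(parts[0])
    gl = np.asarray(rows, dtype=float).reshape(len(rows), n_ind, 3)
    loci = _locus_map_from_markers(ids)
    return GenotypeLikelihoodMatrix(loci, individuals, gl)


def _locus_map_from_markers(ids: list[str]) -> LocusMap:
    chroms, positions = [], []
    for k, marker in enumerate(ids):
        if ":" in marker:
            chrom, _, pos = marker.rpartition(":")
            chroms.append(chrom)
            positions.append(int(pos))
        else:
            chroms.append("un")
            positions.append(k + 1)
    return LocusMap(
        pd.DataFrame(
            {
                "locus_id": ids,
                "chromosome": chroms,
                "position": positions,
                "is_Z": [c in ("Z", "chrZ") for c in chroms],
            }
        )
    )


def _read_vcf(path: str) -> GenotypeLikelihoodMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    rows, ids, chroms, positions = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        try:
            gl = var.format("GL")
        except KeyError:
            gl = None
        if gl is not None:
            like = np.power(10.0, np.asarray(gl, dtype=float))
        else:
            try:
                pl = var.format("PL")
            except KeyError:
                pl = None
            if pl is None:
                n_skipped += 1
                continue
            like = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
        if like.shape[1] != 3:
            n_skipped += 1
            continue
        rows.append(like)
        ids.append(f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
    if n_skipped:
        logger.info("skipped %d non-biallelic or GL-less VCF records", n_skipped)
    loci = LocusMap(
        pd.DataFrame(
            {
                "locus_id": ids,
                "chromosome": chroms,
                "position": positions,
                "is_Z": [c in ("Z", "chrZ") for c in chroms],
            }
        )
    )
    return GenotypeLikelihoodMatrix(loci, individuals, np.asarray(rows))


def read_feature_table(path: str) -> FeatureTable:
    """Read a 4+-column BED-like file into a :class:`FeatureTable`."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >=4 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric start/end") from exc
            records.append(
                {
                    "chromosome": parts[0],
                    "start": start,
                    "end": end,
                    "feature_class": parts[3],
                }
            )
    return FeatureTable(pd.DataFrame(records))


def near_feature(
    loci: LocusMap, features: FeatureTable, window: int = 1000
) -> pd.DataFrame:
    """Flag loci lying in or within ``window`` bp of each feature class.

    A locus at 1-based position P (0-based P-1) is "near" a feature
    [start, end) when P-1 falls in [start - window, end + window). Returns a
    boolean DataFrame indexed like the locus map with one column per
    feature class.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    classes = features.classes
    out = pd.DataFrame(
        False, index=range(len(loci)), columns=classes, dtype=bool
    )
    pos0 = loci.table["position"].to_numpy() - 1  # to 0-based
    chrom = loci.table["chromosome"].to_numpy()
    for fclass in classes:
        sub = features.table[features.table["feature_class"] == fclass]
        for fchrom, grp in sub.groupby("chromosome"):
            on_chrom = chrom == fchrom
            if not on_chrom.any():
                continue
            p = pos0[on_chrom]
            hit = np.zeros(p.shape, dtype=bool)
            for start, end in zip(grp["start"], grp["end"]):
                hit |= (p >= start - window) & (p < end + window)
            out.loc[on_chrom, fclass] = hit
    out.index = loci.table["locus_id"]
    return out


# ---------------------------------------------------------------------------
# Table output with provenance comments


def write_table(df: pd.DataFrame, path: str, config: RunConfig | None = None) -> None:
    """Write a result table as TSV with a config-hash comment header."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# config_hash={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
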