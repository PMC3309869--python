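"""Domain types and I/O for region-based rare-variant association testing.

The central container is :class:`GenotypeMatrix`, an ``n x m`` matrix of
minor-allele counts (each entry in {0, 1, 2}) for ``n`` subjects and ``m``
variants in one tested region, together with :class:`PhenotypeVector` for the
continuous or binary trait.  Collapsing a region's counts into a per-subject
"super variant" (the burden regressor) and column centering live here because
every downstream statistic uses them.

File formats handled:

* genotypes: VCF (biallelic SNVs, GT fields) via cyvcf2, or a tab-separated
  matrix with a ``sample_id`` column followed by one column per variant;
* phenotypes: two tab-separated columns ``sample_id``, ``phenotype``;
* variant sets: two tab-separated columns ``set_id``, ``variant_id`` (one row
  per membership), mirroring common kernel-association setID files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS = "continuous"
BINARY = "binary"

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "VariantSet",
    "load_genotypes",
    "load_phenotypes",
    "load_variant_sets",
    "super_variant",
    "center_columns",
    "CONTINUOUS",
    "BINARY",
]


@dataclass
class VariantSet:
    """A named group of variant IDs tested jointly (a gene or region)."""

    set_id: str
    variant_ids: list

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        if not self.variant_ids:
            raise ValueError(f"empty set: {self.set_id!r}")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError(f"duplicate variant IDs in set {self.set_id!r}")


@dataclass
class GenotypeMatrix:
    """Minor-allele counts for ``n`` subjects at ``m`` variants.

    ``counts[i, j]`` is the number of minor alleles subject ``i`` carries at
    variant ``j`` (0, 1 or 2 under an additive biallelic coding).  Loaders
    enforce minor-allele orientation (no column with allele frequency > 0.5);
    matrices built directly are validated for the {0,1,2} coding only.
    """

    samples: list
    variants: list
    counts: np.ndarray

    def __post_init__(self):
        self.samples = list(self.samples)
        self.variants = list(self.variants)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (samples x variants)")
        n, m = self.counts.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError("counts shape does not match sample/variant IDs")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if m < 1:
            raise ValueError("need at least 1 variant")
        if not np.isin(self.counts, (0, 1, 2)).all():
            raise ValueError("genotype counts must all be in {0, 1, 2}")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def m(self) -> int:
        return self.counts.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Per-variant allele frequency of the counted allele."""
        return self.counts.mean(axis=0) / 2.0

    def restrict(self, variant_ids) -> "GenotypeMatrix":
        """Subset (and reorder) columns to ``variant_ids``."""
        index = {v: j for j, v in enumerate(self.variants)}
        missing = [v for v in variant_ids if v not in index]
        if missing:
            raise KeyError(f"variants absent from source: {missing}")
        cols = [index[v] for v in variant_ids]
        return GenotypeMatrix(self.samples, list(variant_ids),
                              self.counts[:, cols])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, columns=self.variants)
        df.insert(0, "sample_id", self.samples)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        if df.columns[0] != "sample_id":
            raise ValueError("first column of a genotype matrix must be 'sample_id'")
        samples = df["sample_id"].tolist()
        variants = df.columns[1:].tolist()
        raw = df.iloc[:, 1:].to_numpy(dtype=float)
        counts = _resolve_missing(raw, variants)
        counts = _orient_minor(counts, variants)
        return cls(samples, variants, counts.astype(np.int16))


@dataclass
class PhenotypeVector:
    """Length-n trait values, continuous or binary (0/1)."""

    values: np.ndarray
    trait_type: str = CONTINUOUS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.trait_type not in (CONTINUOUS, BINARY):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == BINARY:
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary trait values must be 0/1")
            if self.values.min() == self.values.max():
                raise ValueError("binary trait needs both classes present")
        else:
            if len(self.values) < 2 or np.var(self.values) == 0:
                raise ValueError("continuous trait must have positive variance")

    @property
    def n(self) -> int:
        return len(self.values)


def _resolve_missing(raw: np.ndarray, variants) -> np.ndarray:
    """Impute missing entries to the variant's mean count rounded into {0,1,2}.

    Mean imputation keeps rare-variant burden roughly unbiased; rounding keeps
    the integer coding so downstream invariants hold.
    """
    missing = ~np.isfinite(raw)
    if missing.any():
        col_all_missing = missing.all(axis=0)
        if col_all_missing.any():
            bad = [v for v, b in zip(variants, col_all_missing) if b]
            raise ValueError(f"all-missing variant(s): {bad}")
        col_mean = np.nanmean(raw, axis=0)
        fill = np.clip(np.rint(col_mean), 0, 2)
        raw = np.where(missing, fill[None, :], raw)
        logger.info("imputed %d missing genotype cells", int(missing.sum()))
    if not np.isin(raw, (0.0, 1.0, 2.0)).all():
        raise ValueError("genotype matrix contains non-{0,1,2} entries")
    return raw


def _orient_minor(counts: np.ndarray, variants) -> np.ndarray:
    """Recode g -> 2-g wherever the counted allele has frequency > 0.5.

    Frequencies of exactly 0.5 keep the input orientation (logged); the tests
    are unchanged either way since 2-g is an affine recoding.
    """
    freq = counts.mean(axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        flipped = [v for v, f in zip(variants, flip) if f]
        logger.info("flipped %d major-oriented variant(s) to minor: %s",
                    len(flipped), flipped)
        counts = counts.copy()
        counts[:, flip] = 2 - counts[:, flip]
    ties = np.isclose(freq, 0.5)
    if ties.any():
        logger.info("allele frequency exactly 0.5 at %d variant(s); "
                    "keeping input orientation", int(ties.sum()))
    return counts


def _load_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    variants, columns = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        # gts012: 0/1/2 = ALT count, 3 = missing
        g = rec.gt_types.astype(float)
        g[g == 3] = np.nan
        variants.append(vid)
        columns.append(g)
    if n_multi:
        logger.warning("skipped %d multi-allelic record(s)", n_multi)
    if not variants:
        raise ValueError("no usable biallelic records in VCF")
    raw = np.column_stack(columns)
    counts = _resolve_missing(raw, variants)
    counts = _orient_minor(counts, variants)
    return GenotypeMatrix(samples, variants, counts.astype(np.int16))


def load_genotypes(path, set_def: VariantSet | None = None) -> GenotypeMatrix:
    """Load a genotype source (VCF or TSV matrix), optionally restricted to a set.

    The result is minor-allele oriented with missing entries imputed; when
    ``set_def`` is given, columns follow the set's variant order and every
    requested variant must be present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if ".vcf" in path.name.lower():
        G = _load_vcf(path)
    else:
        G = GenotypeMatrix.from_tsv(path)
    if set_def is not None:
        G = G.restrict(set_def.variant_ids)
    return G


def load_phenotypes(path, samples, trait_type: str | None = None) -> PhenotypeVector:
    """Load a two-column phenotype table and align it to ``samples`` by ID.

    ``trait_type`` is inferred when not given: values all in {0,1} => binary.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if list(df.columns[:2]) != ["sample_id", "phenotype"]:
        raise ValueError("phenotype file must have columns sample_id, phenotype")
    table = dict(zip(df["sample_id"], df["phenotype"].astype(float)))
    missing = [s for s in samples if s not in table]
    if missing:
        raise KeyError(f"phenotype missing for samples: {missing[:5]}")
    values = np.array([table[s] for s in samples], dtype=float)
    if trait_type is None:
        trait_type = BINARY if np.isin(values, (0.0, 1.0)).all() else CONTINUOUS
    return PhenotypeVector(values, trait_type)


def load_variant_sets(path) -> list:
    """Read a setID membership file into an ordered list of VariantSet."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["set_id", "variant_id"]:
        raise ValueError("set file must have columns set_id, variant_id")
    sets = []
    for set_id, grp in df.groupby("set_id", sort=False):
        sets.append(VariantSet(set_id, grp["variant_id"].tolist()))
    return sets


def super_variant(G: GenotypeMatrix) -> np.ndarray:
    """Collapse a region into the per-subject total minor-allele count.

    This row sum is the "super variant" regressor of the burden (Sum) test.
    """
    return G.counts.sum(axis=1).astype(float)


def center_columns(M: np.ndarray) -> np.ndarray:
    """Remove each column's mean: (I - 11'/n) M."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        return M - M.mean()
    return M - M.mean(axis=0, keepdims=True)
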