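"""Haplotype matrices, VCF/TSV round-tripping, contig selection, lineage splits.

Isogenic strains are treated as haploid: a diploid homozygous call collapses
to the single allele it carries, and residual heterozygous calls are handled
by policy (set missing, or raise). Coordinates are 1-based as in VCF and
pairwise distances downstream are plain ``|pos_i - pos_j|`` between point
sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

#: Sampling-locality -> climate-group pooling used throughout (11 localities,
#: 4 groups, from the La Reunion survey design).
CLIMATE_GROUPS = {
    "NB": "cold", "CC": "cold", "CK": "cold",
    "PA": "mid-cold", "TB": "mid-cold", "SS": "mid-cold",
    "CO": "mid-warm", "TK": "mid-warm", "PL": "mid-warm", "GE": "mid-warm",
    "SB": "warm",
}

VALID_LINEAGES = tuple("ABCDEFGH")


class GenotypeError(ValueError):
    """Malformed or inconsistent genotype input."""


class ExcessHeterozygosityError(GenotypeError):
    """A strain's heterozygous-call fraction exceeds the isogenic-line ceiling."""


@dataclass
class HaplotypeMatrix:
    """Strains x biallelic sites over {0, 1, MISSING}.

    Attributes
    ----------
    strains : list of str
        Ordered strain identifiers (rows).
    lineages : list of str
        Lineage label per strain ("?" when unknown).
    contigs : ndarray of str
        Contig identifier per site (columns), grouped contiguously.
    positions : ndarray of int
        1-based bp position per site, strictly increasing within a contig.
    alleles : ndarray of int8, shape (n_strains, n_sites)
        0/1 alleles, MISSING (-1) for no-calls.
    meta : dict
        Free-form provenance (simulation configs, true ancestry tracks, ...).
    """

    strains: list
    lineages: list
    contigs: np.ndarray
    positions: np.ndarray
    alleles: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.strains), len(self.positions)):
            raise GenotypeError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.strains)} strains x {len(self.positions)} sites"
            )
        if len(self.lineages) != len(self.strains):
            raise GenotypeError("one lineage label required per strain")
        for contig in dict.fromkeys(self.contigs):
            pos = self.positions[self.contigs == contig]
            if np.any(np.diff(pos) <= 0):
                raise GenotypeError(
                    f"positions not strictly increasing on contig {contig}"
                )

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def contig_ids(self) -> list:
        """Contig identifiers in order of first appearance."""
        return list(dict.fromkeys(self.contigs))

    def take_sites(self, index) -> "HaplotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            contigs=self.contigs[index],
            positions=self.positions[index],
            alleles=self.alleles[:, index],
            meta=dict(self.meta),
        )

    def take_strains(self, index) -> "HaplotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            strains=[self.strains[i] for i in index],
            lineages=[self.lineages[i] for i in index],
            alleles=self.alleles[index, :],
            meta=dict(self.meta),
        )

    def polymorphic_mask(self) -> np.ndarray:
        """True for sites with minor-allele count >= 1 among non-missing calls."""
        called = self.alleles != MISSING
        ones = ((self.alleles == 1) & called).sum(axis=0)
        n_called = called.sum(axis=0)
        return (ones >= 1) & (ones < n_called) & (n_called >= 1)

    def drop_monomorphic(self) -> "HaplotypeMatrix":
        mask = self.polymorphic_mask()
        dropped = int((~mask).sum())
        if dropped:
            logger.info("dropped %d monomorphic site(s)", dropped)
        out = self.take_sites(np.flatnonzero(mask))
        out.meta["n_monomorphic_dropped"] = dropped
        return out

    def __eq__(self, other):
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.strains == other.strains
            and self.lineages == other.lineages
            and np.array_equal(self.contigs, other.contigs)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.alleles, other.alleles)
        )


def read_metadata(path) -> pd.DataFrame:
    """Read a strain metadata TSV (strain_id, lineage, locality, climate_group).

    The locality -> climate_group mapping must be a function (one group per
    locality) and lineage labels must be single letters A-H.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"strain_id", "lineage", "locality", "climate_group"}
    if not required.issubset(meta.columns):
        raise GenotypeError(f"metadata must have columns {sorted(required)}")
    bad = set(meta["lineage"]) - set(VALID_LINEAGES)
    if bad:
        raise GenotypeError(f"unknown lineage label(s): {sorted(bad)}")
    groups = meta.groupby("locality")["climate_group"].nunique()
    if (groups > 1).any():
        conflicted = groups[groups > 1].index.tolist()
        raise GenotypeError(
            f"locality mapped to multiple climate groups: {conflicted}"
        )
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_haplotypes(vcf_path, het_policy: str = "missing",
                    het_ceiling: float = 0.05) -> HaplotypeMatrix:
    """Read a VCF of isogenic strains into a haploid 0/1 matrix.

    Parameters
    ----------
    het_policy : {"missing", "error"}
        Residual heterozygous calls become missing (default) or raise.
    het_ceiling : float
        Under policy "error", per-strain heterozygous fraction above this
        raises :class:`ExcessHeterozygosityError` (the isogenic-line
        assumption is violated); under "missing" it is only logged.
    """
    if het_policy not in ("missing", "error"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeError(f"no samples in {vcf_path}")

    contigs, positions, columns = [], [], []
    n_dropped_multiallelic = 0
    het_calls = np.zeros(len(samples), dtype=np.int64)
    total_calls = np.zeros(len(samples), dtype=np.int64)
    for var in vcf:
        if len(var.ALT) != 1:
            n_dropped_multiallelic += 1
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1] if a != -1]
            if not alleles:
                col[i] = MISSING
            elif len(set(alleles)) == 1:
                col[i] = alleles[0]
                total_calls[i] += 1
            else:  # heterozygous
                het_calls[i] += 1
                total_calls[i] += 1
                if het_policy == "error":
                    col[i] = MISSING  # counted; ceiling checked after the pass
                else:
                    col[i] = MISSING
        contigs.append(var.CHROM)
        positions.append(var.POS)
        columns.append(col)

    if n_dropped_multiallelic:
        logger.info("dropped %d non-biallelic site(s)", n_dropped_multiallelic)
    if not columns:
        raise GenotypeError(f"no biallelic sites in {vcf_path}")

    het_frac = np.divide(het_calls, np.maximum(total_calls, 1))
    if het_policy == "error" and np.any(het_frac > het_ceiling):
        worst = int(np.argmax(het_frac))
        raise ExcessHeterozygosityError(
            f"excess heterozygosity: strain {samples[worst]} has het fraction "
            f"{het_frac[worst]:.3f} > ceiling {het_ceiling}"
        )
    if np.any(het_frac > het_ceiling):
        for i in np.flatnonzero(het_frac > het_ceiling):
            logger.warning(
                "strain %s het fraction %.3f exceeds ceiling %.3f",
                samples[i], het_frac[i], het_ceiling,
            )

    matrix = HaplotypeMatrix(
        strains=samples,
        lineages=["?"] * len(samples),
        contigs=np.array(contigs, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        alleles=np.stack(columns, axis=1),
    )
    return matrix.drop_monomorphic()


def write_haplotypes(matrix: HaplotypeMatrix, path) -> None:
    """Write a haploid-GT VCF (0, 1, or . per strain); round-trips with
    :func:`read_haplotypes`."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in matrix.contig_ids():
            length = int(matrix.positions[matrix.contigs == contig].max())
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                  "INFO", "FORMAT"] + list(matrix.strains)
        fh.write("\t".join(header) + "\n")
        code = {0: "0", 1: "1", MISSING: "."}
        for j in range(matrix.n_sites):
            calls = [code[int(a)] for a in matrix.alleles[:, j]]
            row = [str(matrix.contigs[j]), str(int(matrix.positions[j])), ".",
                   "A", "T", ".", "PASS", ".", "GT"] + calls
            fh.write("\t".join(row) + "\n")


def attach_metadata(matrix: HaplotypeMatrix, meta: pd.DataFrame) -> HaplotypeMatrix:
    """Fill lineage labels from a metadata table; every strain must be present."""
    lookup = dict(zip(meta["strain_id"], meta["lineage"]))
    missing = [s for s in matrix.strains if s not in lookup]
    if missing:
        raise GenotypeError(f"strain(s) without metadata: {missing}")
    return replace(matrix, lineages=[lookup[s] for s in matrix.strains],
                   meta=dict(matrix.meta))


def select_longest_contigs(matrix: HaplotypeMatrix, k: int = 30) -> HaplotypeMatrix:
    """Retain sites on the k contigs of greatest spanned length.

    Span = max - min observed site position on the contig (assembly lengths
    are not carried by the genotype file). Ties break toward the
    lexicographically smaller contig id. With fewer than k contigs all are
    retained; the operation is idempotent.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    spans = []
    for contig in matrix.contig_ids():
        pos = matrix.positions[matrix.contigs == contig]
        spans.append((-(int(pos.max()) - int(pos.min())), str(contig)))
    keep = {contig for _, contig in sorted(spans)[:k]}
    mask = np.array([str(c) in keep for c in matrix.contigs])
    return matrix.take_sites(np.flatnonzero(mask))


def partition_by_lineage(matrix: HaplotypeMatrix,
                         meta: pd.DataFrame | None = None) -> dict:
    """Split strains by lineage; re-filter sites to within-lineage polymorphism.

    If ``meta`` is given, lineage labels are (re)attached from it first.
    """
    if meta is not None:
        matrix = attach_metadata(matrix, meta)
    if "?" in matrix.lineages:
        unknown = [s for s, l in zip(matrix.strains, matrix.lineages) if l == "?"]
        raise GenotypeError(f"strain(s) without lineage label: {unknown}")
    out = {}
    for lineage in dict.fromkeys(matrix.lineages):
        idx = [i for i, l in enumerate(matrix.lineages) if l == lineage]
        sub = matrix.take_strains(idx)
        out[lineage] = sub.drop_monomorphic()
    return out
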