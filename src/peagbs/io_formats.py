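"""Containers and file formats for reference-free GBS genotype data.

The pipeline works on biallelic SNPs discovered from short sequence "tags"
(consensus reads at a restriction-site locus), so every locus is anchored to a
tag sequence and an allele pair rather than to genome coordinates.  Genotype
calls are stored as the dosage of allele B ``{0, 1, 2}`` with ``-1`` for
missing; the conventional four-state view (homozygous major / heterozygous /
homozygous minor / missing) is derived from per-locus allele frequencies.

Formats handled here:

* long / wide-paired CSV tables of per-(locus, accession) allele read depths,
* tag FASTA with headers ``locusID|offset|A/B`` (64 bp UNEAK dialect, 80 bp
  Stacks dialect),
* TASSEL-style HapMap (11 metadata columns, diploid IUPAC genotype strings,
  ``NN`` missing),
* VCF 4.x via pysam (GT only, ``./.`` missing, POS = tag offset + 1),
* CSV tables for group membership and phenotypes.

Every writer/reader pair round-trips bit-exactly on valid inputs.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# genotype call codes: dosage of allele B, -1 = missing
MISSING: int = -1
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2

UNEAK = "UNEAK"
STACKS = "STACKS"

UNEAK_TAG_LENGTH = 64
STACKS_TAG_LENGTH = 80

_DNA = frozenset("ACGT")

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {kind} identifiers: {sorted(set(dups))[:5]}")


@dataclass
class AlleleDepthMatrix:
    """Per-(locus, accession) read counts for the two alleles of each SNP.

    ``depth_a[i, j]`` / ``depth_b[i, j]`` are the reads supporting allele A /
    allele B of locus ``loci[i]`` in accession ``accessions[j]``.
    """

    loci: list[str]
    accessions: list[str]
    depth_a: np.ndarray
    depth_b: np.ndarray

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        self.accessions = list(self.accessions)
        self.depth_a = np.asarray(self.depth_a, dtype=np.int64)
        self.depth_b = np.asarray(self.depth_b, dtype=np.int64)
        shape = (len(self.loci), len(self.accessions))
        if self.depth_a.shape != shape or self.depth_b.shape != shape:
            raise ValueError(
                f"depth matrices must have shape {shape}, got "
                f"{self.depth_a.shape} and {self.depth_b.shape}"
            )
        if (self.depth_a < 0).any() or (self.depth_b < 0).any():
            raise ValueError("read depths must be non-negative")
        _check_unique(self.loci, "locus")
        _check_unique(self.accessions, "accession")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def total_depth(self) -> np.ndarray:
        return self.depth_a + self.depth_b


@dataclass
class GenotypeMatrix:
    """Loci x accessions genotype calls with per-locus statistics.

    ``calls`` holds the dosage of allele B (``0``, ``1``, ``2``) or ``-1``
    for a missing genotype.  ``mean_depth`` optionally carries the per-locus
    mean read depth over covered cells.
    """

    loci: list[str]
    accessions: list[str]
    calls: np.ndarray
    mean_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.loci = list(self.loci)
        self.accessions = list(self.accessions)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        shape = (len(self.loci), len(self.accessions))
        if self.calls.shape != shape:
            raise ValueError(f"calls must have shape {shape}, got {self.calls.shape}")
        bad = ~np.isin(self.calls, (MISSING, HOM_A, HET, HOM_B))
        if bad.any():
            raise ValueError("calls must be in {-1, 0, 1, 2}")
        _check_unique(self.loci, "locus")
        _check_unique(self.accessions, "accession")
        if self.mean_depth is not None:
            self.mean_depth = np.asarray(self.mean_depth, dtype=float)
            if self.mean_depth.shape != (len(self.loci),):
                raise ValueError("mean_depth must have one entry per locus")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    # ---- per-locus statistics -------------------------------------------

    def n_called(self) -> np.ndarray:
        return (self.calls != MISSING).sum(axis=1)

    def call_rate(self) -> np.ndarray:
        """Fraction of accessions with a non-missing call, per locus."""
        return self.n_called() / max(self.n_accessions, 1)

    def allele_b_freq(self) -> np.ndarray:
        """Frequency of allele B among called genotypes (NaN if none called)."""
        called = self.calls != MISSING
        n = called.sum(axis=1)
        dose = np.where(called, self.calls, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, dose / (2.0 * np.maximum(n, 1)), np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency in [0, 0.5]; 0 for loci with no calls."""
        fb = self.allele_b_freq()
        maf = np.minimum(fb, 1.0 - fb)
        return np.where(np.isnan(maf), 0.0, maf)

    def het_rate(self) -> np.ndarray:
        """Fraction of non-missing calls that are heterozygous (0 if none)."""
        n = self.n_called()
        het = (self.calls == HET).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / np.maximum(n, 1), 0.0)

    def minor_allele_is_b(self) -> np.ndarray:
        """True where allele B is the (weakly) minor allele. Ties go to B."""
        fb = self.allele_b_freq()
        return ~(fb > 0.5)  # NaN -> True

    def minor_dosage(self) -> np.ndarray:
        """Dosage of the per-locus minor allele; missing stays ``-1``."""
        flip = ~self.minor_allele_is_b()
        out = self.calls.copy()
        rows = np.where(flip)[0]
        sub = out[rows]
        sub[sub >= 0] = 2 - sub[sub >= 0]
        out[rows] = sub
        return out

    # ---- manipulation ----------------------------------------------------

    def subset_loci(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.where(keep)[0]
        else:
            pos = {l: i for i, l in enumerate(self.loci)}
            idx = np.array([pos[l] for l in keep], dtype=int)
        md = self.mean_depth[idx] if self.mean_depth is not None else None
        return GenotypeMatrix(
            [self.loci[i] for i in idx], self.accessions, self.calls[idx], md
        )

    def subset_accessions(self, keep: Sequence[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.accessions)}
        idx = np.array([pos[a] for a in keep], dtype=int)
        return GenotypeMatrix(
            self.loci, list(keep), self.calls[:, idx], self.mean_depth
        )

    def accession_indices(self, accessions: Sequence[str]) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.accessions)}
        try:
            return np.array([pos[a] for a in accessions], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown accession {exc.args[0]!r}") from None

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.loci == other.loci
            and self.accessions == other.accessions
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class TagRecord:
    """One SNP locus: consensus tag sequence, SNP offset and allele pair."""

    locus_id: str
    tag_sequence: str
    snp_offset: int
    allele_a: str
    allele_b: str
    source: str  # UNEAK or STACKS

    def __post_init__(self) -> None:
        if not set(self.tag_sequence) <= _DNA:
            raise ValueError(
                f"{self.locus_id}: tag contains non-ACGT characters"
            )
        if not 0 <= self.snp_offset < len(self.tag_sequence):
            raise ValueError(
                f"{self.locus_id}: SNP offset {self.snp_offset} outside tag of "
                f"length {len(self.tag_sequence)}"
            )
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.locus_id}: alleles must differ")
        for a in (self.allele_a, self.allele_b):
            if a not in _DNA:
                raise ValueError(f"{self.locus_id}: invalid allele {a!r}")
        if self.source not in (UNEAK, STACKS):
            raise ValueError(f"{self.locus_id}: unknown source {self.source!r}")


class TagCatalog:
    """An ordered collection of :class:`TagRecord` with unique locus ids."""

    def __init__(self, records: Sequence[TagRecord]):
        self.records: list[TagRecord] = list(records)
        _check_unique([r.locus_id for r in self.records], "locus")
        self._by_id: dict[str, TagRecord] = {r.locus_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TagRecord]:
        return iter(self.records)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._by_id

    def __getitem__(self, locus_id: str) -> TagRecord:
        try:
            return self._by_id[locus_id]
        except KeyError:
            raise KeyError(f"locus {locus_id!r} not in catalog") from None

    @property
    def loci(self) -> list[str]:
        return [r.locus_id for r in self.records]

    def subset(self, loci: Sequence[str]) -> "TagCatalog":
        return TagCatalog([self[l] for l in loci])


@dataclass
class GroupTable:
    """Accession -> genetic-group label with availability and membership Q.

    ``membership_q`` is carried metadata from an upstream structure analysis;
    group assignment itself happens before this table is built.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate accessions in group table")
        if "group" not in t.columns:
            raise ValueError("group table needs a 'group' column")
        if "available" not in t.columns:
            t = t.assign(available=True)
        if "membership_q" not in t.columns:
            t = t.assign(membership_q=np.nan)
        q = t["membership_q"].to_numpy(dtype=float)
        ok = np.isnan(q) | ((q >= 0) & (q <= 1))
        if not ok.all():
            raise ValueError("membership_q must lie in [0, 1]")
        self.table = t[["group", "available", "membership_q"]].copy()
        self.table["available"] = self.table["available"].astype(bool)

    @property
    def accessions(self) -> list[str]:
        return list(self.table.index)

    @property
    def labels(self) -> list[str]:
        # first-appearance order, deterministic
        seen: dict[str, None] = {}
        for g in self.table["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def members(self, label: str) -> list[str]:
        if label not in set(self.table["group"]):
            raise KeyError(f"unknown group label {label!r}")
        return list(self.table.index[self.table["group"] == label])

    def available_accessions(self) -> list[str]:
        return list(self.table.index[self.table["available"]])


# ---------------------------------------------------------------------------
# depth tables
# ---------------------------------------------------------------------------

def read_depth_table(path: str | Path, dialect: str = "long") -> AlleleDepthMatrix:
    """Read a per-(locus, accession) allele read-depth table.

    ``long`` dialect: header ``locus,accession,count_a,count_b``, one row per
    covered cell; unlisted cells are (0, 0).  ``wide-paired`` dialect: one row
    per locus, first column ``locus``, then ``<accession>:a``/``<accession>:b``
    column pairs.
    """
    path = Path(path)
    if dialect == "long":
        return _read_depth_long(path)
    if dialect == "wide-paired":
        return _read_depth_wide(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_depth_long(path: Path) -> AlleleDepthMatrix:
    cells: dict[tuple[str, str], tuple[int, int]] = {}
    loci: dict[str, None] = {}
    accessions: dict[str, None] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: no records")
        expected = ["locus", "accession", "count_a", "count_b"]
        if [h.strip() for h in header] != expected:
            raise ValueError(
                f"{path}: line 1: expected header {','.join(expected)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 fields")
            locus, acc = row[0].strip(), row[1].strip()
            try:
                a, b = int(row[2]), int(row[3])
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: counts must be integers"
                ) from None
            if a < 0 or b < 0:
                raise ValueError(f"{path}: line {lineno}: negative count")
            if (locus, acc) in cells:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate cell ({locus}, {acc})"
                )
            cells[(locus, acc)] = (a, b)
            loci.setdefault(locus, None)
            accessions.setdefault(acc, None)
    if not cells:
        raise ValueError(f"{path}: no records")
    loci_l, acc_l = list(loci), list(accessions)
    li = {l: i for i, l in enumerate(loci_l)}
    ai = {a: i for i, a in enumerate(acc_l)}
    da = np.zeros((len(loci_l), len(acc_l)), dtype=np.int64)
    db = np.zeros_like(da)
    for (locus, acc), (a, b) in cells.items():
        da[li[locus], ai[acc]] = a
        db[li[locus], ai[acc]] = b
    return AlleleDepthMatrix(loci_l, acc_l, da, db)


def _read_depth_wide(path: Path) -> AlleleDepthMatrix:
    df = pd.read_csv(path)
    if df.empty or df.shape[1] < 3:
        raise ValueError(f"{path}: no records")
    if df.columns[0] != "locus":
        raise ValueError(f"{path}: first column must be 'locus'")
    cols = list(df.columns[1:])
    accs: list[str] = []
    for i in range(0, len(cols), 2):
        if i + 1 >= len(cols):
            raise ValueError(f"{path}: unpaired depth column {cols[i]!r}")
        ca, cb = cols[i], cols[i + 1]
        if not (ca.endswith(":a") and cb.endswith(":b") and ca[:-2] == cb[:-2]):
            raise ValueError(f"{path}: columns {ca!r},{cb!r} are not an a/b pair")
        accs.append(ca[:-2])
    da = df[[f"{a}:a" for a in accs]].to_numpy(dtype=np.int64)
    db = df[[f"{a}:b" for a in accs]].to_numpy(dtype=np.int64)
    return AlleleDepthMatrix(list(df["locus"].astype(str)), accs, da, db)


def write_depth_table(
    adm: AlleleDepthMatrix, path: str | Path, dialect: str = "long"
) -> None:
    """Write a depth table; the long dialect omits (0, 0) cells."""
    path = Path(path)
    if dialect == "long":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["locus", "accession", "count_a", "count_b"])
            for i, locus in enumerate(adm.loci):
                for j, acc in enumerate(adm.accessions):
                    a, b = adm.depth_a[i, j], adm.depth_b[i, j]
                    if a or b:
                        w.writerow([locus, acc, int(a), int(b)])
    elif dialect == "wide-paired":
        data: dict[str, object] = {"locus": adm.loci}
        for j, acc in enumerate(adm.accessions):
            data[f"{acc}:a"] = adm.depth_a[:, j]
            data[f"{acc}:b"] = adm.depth_b[:, j]
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# HapMap
# ---------------------------------------------------------------------------

def _hapmap_genotype_strings(a: str, b: str) -> dict[int, str]:
    het = "".join(sorted(a + b))  # alphabetical, deterministic output
    return {HOM_A: a + a, HET: het, HOM_B: b + b, MISSING: "NN"}


def write_hapmap(gm: GenotypeMatrix, catalog: TagCatalog, path: str | Path) -> None:
    """Write a TASSEL-style HapMap file (tab-separated, ``NN`` missing).

    Allele identities come from ``catalog``; every locus of ``gm`` must be
    present there.  ``chrom`` is the tag locus id and ``pos`` the 1-based SNP
    offset within the tag (tags have no genome coordinates).
    """
    missing = [l for l in gm.loci if l not in catalog]
    if missing:
        raise KeyError(f"loci absent from catalog: {missing[:5]}")
    with open(path, "w") as fh:
        fh.write("\t".join(HAPMAP_COLUMNS + gm.accessions) + "\n")
        for i, locus in enumerate(gm.loci):
            rec = catalog[locus]
            geno = _hapmap_genotype_strings(rec.allele_a, rec.allele_b)
            row = [
                locus, f"{rec.allele_a}/{rec.allele_b}", locus,
                str(rec.snp_offset + 1), "+", "NA", "NA", "NA", "NA", "NA", "NA",
            ]
            row.extend(geno[int(c)] for c in gm.calls[i])
            fh.write("\t".join(row) + "\n")


def read_hapmap(path: str | Path) -> GenotypeMatrix:
    """Read a HapMap file written by :func:`write_hapmap`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(HAPMAP_COLUMNS)] != HAPMAP_COLUMNS:
            raise ValueError(f"{path}: not a HapMap file")
        accessions = header[len(HAPMAP_COLUMNS):]
        loci: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}: line {lineno}: wrong field count")
            locus, alleles = parts[0], parts[1]
            try:
                a, b = alleles.split("/")
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: bad alleles field {alleles!r}"
                ) from None
            decode = {s: c for c, s in _hapmap_genotype_strings(a, b).items()}
            # accept either base order for heterozygotes
            decode[a + b] = HET
            decode[b + a] = HET
            try:
                calls = np.array(
                    [decode[g] for g in parts[len(HAPMAP_COLUMNS):]], dtype=np.int8
                )
            except KeyError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: unknown genotype {exc.args[0]!r}"
                ) from None
            loci.append(locus)
            rows.append(calls)
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(accessions)), dtype=np.int8)
    )
    return GenotypeMatrix(loci, accessions, calls)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(gm: GenotypeMatrix, catalog: TagCatalog, path: str | Path) -> None:
    """Write genotypes as VCF 4.x (GT only; CHROM = locus id, POS = offset+1)."""
    missing = [l for l in gm.loci if l not in catalog]
    if missing:
        raise KeyError(f"loci absent from catalog: {missing[:5]}")
    header = pysam.VariantHeader()
    header.add_meta("source", "peagbs")
    for locus in gm.loci:
        header.contigs.add(locus, length=len(catalog[locus].tag_sequence))
    header.add_meta(
        "FORMAT",
        items=[("ID", "GT"), ("Number", "1"), ("Type", "String"),
               ("Description", "Genotype")],
    )
    for acc in gm.accessions:
        header.add_sample(acc)
    gt_map = {HOM_A: (0, 0), HET: (0, 1), HOM_B: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, locus in enumerate(gm.loci):
            rec_info = catalog[locus]
            rec = vf.new_record(
                contig=locus,
                start=rec_info.snp_offset,
                stop=rec_info.snp_offset + 1,
                alleles=(rec_info.allele_a, rec_info.allele_b),
                id=locus,
            )
            for j, acc in enumerate(gm.accessions):
                rec.samples[acc]["GT"] = gt_map[int(gm.calls[i, j])]
            vf.write(rec)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a GT-only VCF into a :class:`GenotypeMatrix`."""
    with pysam.VariantFile(str(path)) as vf:
        accessions = list(vf.header.samples)
        loci: list[str] = []
        rows: list[np.ndarray] = []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{path}: {rec.chrom} is not a biallelic SNP")
            calls = np.empty(len(accessions), dtype=np.int8)
            for j, acc in enumerate(accessions):
                gt = rec.samples[acc]["GT"]
                if gt is None or any(g is None for g in gt):
                    calls[j] = MISSING
                else:
                    calls[j] = int(sum(gt))
            loci.append(rec.chrom)
            rows.append(calls)
    calls = (
        np.vstack(rows) if rows else np.empty((0, len(accessions)), dtype=np.int8)
    )
    return GenotypeMatrix(loci, accessions, calls)


# ---------------------------------------------------------------------------
# tag FASTA
# ---------------------------------------------------------------------------

def read_tag_fasta(path: str | Path) -> TagCatalog:
    """Read tag consensus sequences; headers follow ``locusID|offset|A/B``.

    Pipeline of origin is inferred from tag length: 64 bp -> UNEAK,
    80 bp -> Stacks.
    """
    records: list[TagRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) != 3 or "/" not in parts[2]:
            raise ValueError(f"{path}: bad header {rec.id!r}")
        locus, offset_s, alleles = parts
        a, b = alleles.split("/")
        try:
            offset = int(offset_s)
        except ValueError:
            raise ValueError(f"{path}: bad offset in header {rec.id!r}") from None
        if locus in seen:
            raise ValueError(f"{path}: duplicate locus {locus!r}")
        seen.add(locus)
        seq = str(rec.seq).upper()
        if len(seq) == UNEAK_TAG_LENGTH:
            source = UNEAK
        elif len(seq) == STACKS_TAG_LENGTH:
            source = STACKS
        else:
            raise ValueError(
                f"{path}: {locus}: tag length {len(seq)} is neither "
                f"{UNEAK_TAG_LENGTH} (UNEAK) nor {STACKS_TAG_LENGTH} (Stacks)"
            )
        records.append(TagRecord(locus, seq, offset, a, b, source))
    return TagCatalog(records)


def write_tag_fasta(catalog: TagCatalog, path: str | Path) -> None:
    recs = [
        SeqRecord(
            Seq(r.tag_sequence),
            id=f"{r.locus_id}|{r.snp_offset}|{r.allele_a}/{r.allele_b}",
            description="",
        )
        for r in catalog
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# metadata CSVs
# ---------------------------------------------------------------------------

def read_groups(path: str | Path) -> GroupTable:
    df = pd.read_csv(path, index_col="accession")
    return GroupTable(df)


def write_groups(groups: GroupTable, path: str | Path) -> None:
    groups.table.to_csv(path, index_label="accession")


def read_phenotype(path: str | Path) -> pd.Series:
    """Read a two-column accession/value CSV; 'NA' becomes NaN."""
    df = pd.read_csv(path, index_col="accession")
    if "value" not in df.columns:
        raise ValueError(f"{path}: phenotype CSV needs a 'value' column")
    return df["value"].astype(float)


def write_phenotype(pheno: pd.Series, path: str | Path) -> None:
    pheno.rename("value").to_csv(path, index_label="accession", na_rep="NA")
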