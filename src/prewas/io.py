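"""Readers for the standard input formats and writers for output matrices.

VCF v4.x (plain or bgzipped, via pysam), GFF3 gene annotation and newick
trees come in; tab-delimited 0/1 matrices and log tables go out.  All
coordinates are 1-based throughout (VCF convention; GFF intervals are
1-based inclusive).
"""

from __future__ import annotations

import dataclasses
import logging
import re
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .phylo import Phylogeny

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call ("." / "./." / half calls / "*")
MISSING = -1


class VcfParseError(ValueError):
    pass


class VcfValidationError(ValueError):
    pass


class GffValidationError(ValueError):
    pass


class TreeValidationError(ValueError):
    pass


@dataclasses.dataclass
class VariantRecord:
    """One genomic position of the merged multi-sample VCF.

    ``calls`` holds one allele index per sample: 0 = ref, i >= 1 =
    ``alts[i-1]``, :data:`MISSING` for no call.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    calls: list[int]
    ann: list[str] = dataclasses.field(default_factory=list)

    def allele(self, call: int) -> str:
        if call == MISSING:
            return "N"
        return self.ref if call == 0 else self.alts[call - 1]


@dataclasses.dataclass
class VariantTable:
    samples: list[str]
    records: list[VariantRecord]

    @property
    def contigs(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.chrom, None)
        return list(seen)


@dataclasses.dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    strand: str = "."


def _collapse_gt(gt: tuple | None, n_alleles: int, where: str) -> int:
    """Collapse a pysam GT tuple to a single haploid allele index.

    Clonal bacterial data is expected: homozygous diploid encodings
    ("1/1") collapse to the allele, heterozygous ones ("0/1") become
    MISSING with a warning.
    """
    if gt is None:
        return MISSING
    idx = [a for a in gt if a is not None]
    if not idx:
        return MISSING
    if len(set(idx)) > 1:
        warnings.warn(f"heterozygous genotype {gt} at {where} treated as "
                      "missing (clonal data expected)")
        return MISSING
    call = int(idx[0])
    if call >= n_alleles:
        raise VcfValidationError(
            f"genotype index {call} out of range of ALT list at {where}")
    return call


def _merge_cosited(records: list[VariantRecord], samples: Sequence[str],
                   ) -> VariantRecord:
    """Re-merge pre-split biallelic lines that share one (chrom, pos).

    ALT lists are unioned in order of appearance and call indices remapped.
    A sample carrying different alternate alleles on different lines is a
    contradiction and raises.
    """
    first = records[0]
    for r in records[1:]:
        if r.ref != first.ref:
            raise VcfValidationError(
                f"conflicting REF alleles at {first.chrom}:{first.pos}: "
                f"{first.ref!r} vs {r.ref!r}")
    alts: list[str] = []
    for r in records:
        for a in r.alts:
            if a not in alts:
                alts.append(a)
    calls: list[int] = []
    for j in range(len(samples)):
        seen_alts = {alts.index(r.alts[r.calls[j] - 1]) + 1
                     for r in records if r.calls[j] >= 1}
        if len(seen_alts) > 1:
            raise VcfValidationError(
                f"sample {samples[j]!r} carries conflicting alternate "
                f"alleles at {first.chrom}:{first.pos}")
        if seen_alts:
            calls.append(seen_alts.pop())
        elif any(r.calls[j] == 0 for r in records):
            calls.append(0)
        else:
            calls.append(MISSING)
    ann = [a for r in records for a in r.ann]
    return VariantRecord(chrom=first.chrom, pos=first.pos, ref=first.ref,
                         alts=alts, calls=calls, ann=ann)


def read_multivcf(path: str | Path) -> VariantTable:
    """Read a merged multi-sample VCF into a :class:`VariantTable`.

    One record per distinct (chrom, pos): lines pre-split per alternate
    allele (``bcftools norm -m-`` style) at the same position are re-merged
    with their ALT lists unioned.  SnpEff ``ANN`` INFO strings are captured
    verbatim.  Spanning-deletion alleles ("*") are treated as missing data
    and dropped from the ALT list.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.header.samples)
    if not samples:
        raise VcfValidationError("VCF has no sample columns")
    dupes = {s for s in samples if samples.count(s) > 1}
    if dupes:
        raise VcfValidationError(
            "duplicate sample names: " + ", ".join(sorted(dupes)))

    records: list[VariantRecord] = []
    lineno = 0
    it = iter(vcf)
    while True:
        lineno += 1
        try:
            rec = next(it)
        except StopIteration:
            break
        except (OSError, ValueError) as exc:
            raise VcfParseError(
                f"malformed VCF record at data line {lineno}: {exc}") from exc
        where = f"{rec.chrom}:{rec.pos} (data line {lineno})"
        alts = list(rec.alts or ())
        if not alts:
            raise VcfValidationError(f"empty ALT field at {where}")
        star = [i for i, a in enumerate(alts) if a == "*"]
        keep = [a for a in alts if a != "*"]
        if any(a == rec.ref for a in keep):
            raise VcfValidationError(f"ALT equals REF at {where}")
        calls = []
        for s in samples:
            call = _collapse_gt(rec.samples[s].get("GT"), 1 + len(alts),
                                f"{where} sample {s}")
            if call >= 1 and (call - 1) in star:
                logger.info("spanning deletion '*' at %s treated as missing",
                            where)
                call = MISSING
            elif call >= 1:
                call = keep.index(alts[call - 1]) + 1
            calls.append(call)
        if not keep:
            warnings.warn(f"site {where} has no alternate alleles after "
                          "removing '*'; skipped")
            continue
        ann_raw = rec.info.get("ANN") if "ANN" in rec.info else None
        if ann_raw is None:
            ann = []
        elif isinstance(ann_raw, str):
            ann = [ann_raw]
        else:
            ann = list(ann_raw)
        records.append(VariantRecord(chrom=rec.chrom, pos=rec.pos,
                                     ref=rec.ref, alts=keep, calls=calls,
                                     ann=ann))
    vcf.close()

    by_site: dict[tuple[str, int], list[VariantRecord]] = {}
    order: list[tuple[str, int]] = []
    for r in records:
        key = (r.chrom, r.pos)
        if key not in by_site:
            order.append(key)
        by_site.setdefault(key, []).append(r)
    merged = [
        by_site[key][0] if len(by_site[key]) == 1
        else _merge_cosited(by_site[key], samples)
        for key in order
    ]
    return VariantTable(samples=samples, records=merged)


_GFF_COLUMNS = ["chrom", "source", "type", "start", "end", "score",
                "strand", "phase", "attributes"]


def _gff_attr(attributes: str, key: str) -> str | None:
    m = re.search(rf"(?:^|;)\s*{key}=([^;]+)", attributes)
    return m.group(1).strip() if m else None


def read_gff(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Read gene intervals from a GFF3 file.

    Rows whose type column contains ``feature_type`` (default "gene";
    pass "CDS" to use CDS features) are kept; header/comment lines are
    skipped.  Coordinates are preserved exactly as printed (1-based
    inclusive).  Overlapping genes are permitted and expected.  Features
    without an ``ID`` or ``locus_tag`` attribute get a synthesized id.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=_GFF_COLUMNS,
                     dtype={"chrom": str, "start": int, "end": int})
    if feature_type == "CDS":
        df = df[df["type"] == "CDS"]
    else:
        df = df[df["type"].str.contains(feature_type, case=False, na=False)]
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.start > row.end:
            raise GffValidationError(
                f"gene interval start > end at {row.chrom}:{row.start}-{row.end}")
        gid = _gff_attr(row.attributes, "ID") or _gff_attr(row.attributes,
                                                           "locus_tag")
        if gid is None:
            gid = f"gene_{row.chrom}_{row.start}_{row.end}"
            warnings.warn(f"feature at {row.chrom}:{row.start}-{row.end} has "
                          f"no ID/locus_tag; synthesized id {gid!r}")
        if gid in seen:
            raise GffValidationError(f"duplicate gene id {gid!r} in annotation")
        seen.add(gid)
        strand = row.strand if row.strand in ("+", "-") else "."
        genes.append(GeneRecord(gene_id=gid, chrom=str(row.chrom),
                                start=int(row.start), end=int(row.end),
                                strand=strand))
    return genes


def read_tree(path: str | Path, samples: Sequence[str] | None = None
              ) -> Phylogeny:
    """Read a newick tree; optionally check its tips cover the sample set."""
    tree = dendropy_read(path)
    phy = Phylogeny(tree)
    if samples is not None:
        missing = sorted(set(samples) - set(phy.tip_labels))
        if missing:
            raise TreeValidationError(
                "tree is missing sample tips: " + ", ".join(missing))
    return phy


def dendropy_read(path: str | Path):
    import dendropy
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_matrix(matrix: pd.DataFrame, path: str | Path,
                 format: str = "tsv") -> None:
    """Write a labelled 0/1 matrix as a tab-delimited file.

    ``tsv`` names the key column after the matrix index (default "id");
    ``rtab`` uses the Roary-style "Gene" key column.  Output is
    byte-identical across runs for identical input.
    """
    if format not in ("tsv", "rtab"):
        raise ValueError(f"unknown matrix format {format!r}")
    out = matrix.copy()
    out.index.name = "Gene" if format == "rtab" else (matrix.index.name or "id")
    out.to_csv(path, sep="\t", lineterminator="\n")
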