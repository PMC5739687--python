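"""Containers and readers/writers for the formats the pipeline touches.

Matrices travel as TSV (features x samples, empty cell = missing — never a
zero or sentinel, since downstream log transforms would corrupt those), gene
sets as GMT, mtDNA variants as VCF 4.2 (chrom MT, per-sample AD) or TSV,
nuclear variants as TSV with a patient column, CNV segments as BED3+.
Variant coordinates are 1-based inclusive (VCF convention); CNV segments are
0-based half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .mtdna import MT_GENOME_LENGTH, MtVariant
from .nuclear import CnvSegment, NuclearVariant

GROUPS = ("tumor", "normal")


# ---------------------------------------------------------------------------
# OmicsMatrix
# ---------------------------------------------------------------------------
@dataclass
class OmicsMatrix:
    """A paired tumor/normal feature-by-sample abundance table.

    ``values`` is a DataFrame (features x samples) with NaN for missing
    cells.  ``groups`` maps each sample to ``tumor``/``normal`` and
    ``pairs`` to its patient; every patient must contribute exactly one
    sample per group.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    pairs: dict[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        per_patient: dict[str, set[str]] = {}
        for sample in self.values.columns:
            if sample not in self.groups:
                raise KeyError(f"sample {sample!r} missing from group map")
            if sample not in self.pairs:
                raise KeyError(f"sample {sample!r} missing from pair map")
            if self.groups[sample] not in GROUPS:
                raise ValueError(f"invalid group {self.groups[sample]!r}")
            per_patient.setdefault(self.pairs[sample], set()).add(self.groups[sample])
        for patient, seen in per_patient.items():
            if seen != set(GROUPS):
                raise ValueError(
                    f"patient {patient!r} lacks a complete tumor/normal pair"
                )

    # -- views -------------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def patients(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if self.pairs[s] not in seen:
                seen.append(self.pairs[s])
        return seen

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def tumor_values(self) -> pd.DataFrame:
        return self.values[self.samples_of("tumor")]

    def normal_values(self) -> pd.DataFrame:
        return self.values[self.samples_of("normal")]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        return OmicsMatrix(values, dict(self.groups), dict(self.pairs))

    def subset(self, features: Sequence[str]) -> "OmicsMatrix":
        return self.with_values(self.values.loc[list(features)])


def read_matrix(
    path: str | Path,
    group_map: Mapping[str, str],
    pair_map: Mapping[str, str],
) -> OmicsMatrix:
    """Read a feature-by-sample TSV; empty cells become missing (NaN)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return OmicsMatrix(frame, dict(group_map), dict(pair_map))


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------
@dataclass
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        # preserve first-occurrence order while collapsing duplicates
        object.__setattr__(self, "members", tuple(dict.fromkeys(self.members)))
        if len(self.members) < 1:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, gene_set: GeneSet) -> None:
        self.sets[gene_set.name] = gene_set


def read_gmt(path: str | Path) -> GeneSetCollection:
    collection = GeneSetCollection()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line for {parts[0]!r} has no members")
        collection.add(GeneSet(parts[0], parts[1], tuple(parts[2:])))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([gs.name, gs.description, *gs.members]) for gs in collection
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# mtDNA variants — VCF 4.2 and TSV
# ---------------------------------------------------------------------------
_MT_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    f"##contig=<ID=MT,length={MT_GENOME_LENGTH}>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
)


def write_mt_vcf(variants: Sequence[MtVariant], path: str | Path) -> None:
    """Write one patient's paired mtDNA variants as a two-sample VCF.

    Samples are named TUMOR and NORMAL; a variant undetected in normal gets
    a missing AD in that sample.
    """
    lines = [_MT_VCF_HEADER.rstrip("\n")]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL")

    def fmt(ad: tuple[int, int] | None) -> str:
        if ad is None:
            return "./.:.,."
        return f"0/1:{ad[0]},{ad[1]}"

    for v in sorted(variants, key=lambda v: v.position):
        lines.append(
            f"MT\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:AD\t"
            f"{fmt(v.tumor_ad)}\t{fmt(v.normal_ad)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_mt_vcf(path: str | Path, patient: str | None = None) -> list[MtVariant]:
    """Read paired mtDNA variants from a VCF with TUMOR/NORMAL samples and AD."""
    variants: list[MtVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if "TUMOR" not in samples or "NORMAL" not in samples:
            raise ValueError("mtDNA VCF must carry TUMOR and NORMAL samples")
        for record in vcf:
            if record.pos > MT_GENOME_LENGTH:
                raise ValueError(
                    f"position {record.pos} beyond rCRS length {MT_GENOME_LENGTH}"
                )

            def ad_of(sample: str) -> tuple[int, int] | None:
                ad = record.samples[sample].get("AD")
                if ad is None or any(x is None for x in ad):
                    return None
                return int(ad[0]), int(ad[1])

            tumor_ad = ad_of("TUMOR")
            if tumor_ad is None:
                raise ValueError(
                    f"missing AD for TUMOR at MT:{record.pos}; cannot compute HF"
                )
            variants.append(
                MtVariant(
                    position=record.pos,
                    ref=record.ref,
                    alt=record.alts[0],
                    patient=patient,
                    tumor_ad=tumor_ad,
                    normal_ad=ad_of("NORMAL"),
                )
            )
    return variants


_MT_TSV_COLUMNS = (
    "patient", "position", "ref", "alt",
    "tumor_ref_count", "tumor_alt_count", "normal_ref_count", "normal_alt_count",
    "gene", "functional_class", "nucleotide_variability", "disease_score",
    "rna_prediction_score", "haplogroup_defining", "origin",
)


def write_mt_tsv(variants: Sequence[MtVariant], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append({
            "patient": v.patient,
            "position": v.position,
            "ref": v.ref,
            "alt": v.alt,
            "tumor_ref_count": v.tumor_ad[0] if v.tumor_ad else None,
            "tumor_alt_count": v.tumor_ad[1] if v.tumor_ad else None,
            "normal_ref_count": v.normal_ad[0] if v.normal_ad else None,
            "normal_alt_count": v.normal_ad[1] if v.normal_ad else None,
            "gene": v.gene,
            "functional_class": v.functional_class,
            "nucleotide_variability": v.nucleotide_variability,
            "disease_score": v.disease_score,
            "rna_prediction_score": v.rna_prediction_score,
            "haplogroup_defining": int(v.haplogroup_defining),
            "origin": v.origin,
        })
    pd.DataFrame(rows, columns=list(_MT_TSV_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_mt_tsv(path: str | Path) -> list[MtVariant]:
    frame = pd.read_csv(path, sep="\t")

    def opt(row, col):
        val = row[col]
        return None if pd.isna(val) else val

    variants = []
    for _, row in frame.iterrows():
        tumor_ad = None
        if not pd.isna(row["tumor_ref_count"]):
            tumor_ad = (int(row["tumor_ref_count"]), int(row["tumor_alt_count"]))
        normal_ad = None
        if not pd.isna(row["normal_ref_count"]):
            normal_ad = (int(row["normal_ref_count"]), int(row["normal_alt_count"]))
        variants.append(
            MtVariant(
                position=int(row["position"]),
                ref=row["ref"],
                alt=row["alt"],
                patient=opt(row, "patient"),
                tumor_ad=tumor_ad,
                normal_ad=normal_ad,
                gene=opt(row, "gene"),
                functional_class=opt(row, "functional_class"),
                nucleotide_variability=opt(row, "nucleotide_variability"),
                disease_score=opt(row, "disease_score"),
                rna_prediction_score=opt(row, "rna_prediction_score"),
                haplogroup_defining=bool(int(row["haplogroup_defining"])),
                origin=row["origin"],
            )
        )
    return variants


# ---------------------------------------------------------------------------
# nuclear variants / CNV segments
# ---------------------------------------------------------------------------
def write_nuclear_tsv(variants: Sequence[NuclearVariant], path: str | Path) -> None:
    rows = [
        {"patient": v.patient, "chrom": v.chrom, "pos": v.pos,
         "ref": v.ref, "alt": v.alt, "effect_class": v.effect_class}
        for v in variants
    ]
    pd.DataFrame(
        rows, columns=["patient", "chrom", "pos", "ref", "alt", "effect_class"]
    ).to_csv(path, sep="\t", index=False)


def read_nuclear_tsv(path: str | Path) -> list[NuclearVariant]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        NuclearVariant(
            patient=row["patient"], chrom=row["chrom"], pos=int(row["pos"]),
            ref=row["ref"], alt=row["alt"], effect_class=row["effect_class"],
        )
        for _, row in frame.iterrows()
    ]


def write_cnv_bed(segments: Sequence[CnvSegment], path: str | Path) -> None:
    """BED3 + copy_state + patient columns, 0-based half-open."""
    lines = [
        f"{s.chrom}\t{s.start}\t{s.end}\t{s.copy_state}\t{s.patient or '.'}"
        for s in segments
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_cnv_bed(path: str | Path) -> list[CnvSegment]:
    segments = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end, copy_state, patient = line.split("\t")[:5]
        segments.append(
            CnvSegment(
                chrom=chrom, start=int(start), end=int(end),
                copy_state=int(copy_state),
                patient=None if patient == "." else patient,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------
def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """Protein annotation TSV: feature_id, is_mito, complex, is_assembly (+ location)."""
    annotation.to_csv(path, sep="\t", index=True, index_label="feature_id")


def read_annotation(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col="feature_id")
    frame["is_mito"] = frame["is_mito"].astype(bool)
    if "is_assembly" in frame:
        frame["is_assembly"] = frame["is_assembly"].astype(bool)
    if "complex" in frame:
        frame["complex"] = frame["complex"].fillna("")
    return frame
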