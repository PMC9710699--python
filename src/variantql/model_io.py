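"""Parsing of VCF, PED and annotation strings into normalized domain records.

Multi-allelic VCF records are decomposed into one record per ALT allele so
that ``(chrom, pos, ref, alt)`` is a primary key.  Genotypes are re-encoded
per decomposed allele as an alt-allele count: ``-1`` unknown, ``0`` hom-ref,
``1`` het, ``2`` hom-alt.  SnpEff ``ANN`` and VEP ``CSQ`` INFO strings are
split into per-transcript annotation records using the pipe-format clause
declared in the VCF header.
"""

from __future__ import annotations

import gzip
import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "FieldDescriptor",
    "VariantRecord",
    "AnnotationRecord",
    "SampleGenotype",
    "PedigreeEntry",
    "ImportReport",
    "VcfSchema",
    "MalformedHeaderError",
    "PedError",
    "normalize_name",
    "parse_vcf_header",
    "parse_snpeff_ann",
    "parse_vep_csq",
    "encode_genotype",
    "decompose_record",
    "parse_ped",
    "import_vcf",
]

#: VCF header Type -> internal value type.
_TYPE_MAP = {
    "Integer": "int",
    "Float": "float",
    "Flag": "bool",
    "String": "string",
    "Character": "string",
}

#: Annotator column names normalized to the shared queryable vocabulary.
#: Covers both SnpEff (Annotation/Annotation_Impact/Gene_Name) and VEP
#: (Consequence/IMPACT/SYMBOL) dialects; names are compared lowercased.
ANNOTATION_NAME_ALIASES = {
    "annotation": "consequence",
    "annotation_impact": "impact",
    "gene_name": "gene",
    "symbol": "gene",
    "feature_id": "transcript",
    "feature": "transcript",
}

CORE_FIELD_NAMES = ("chrom", "pos", "ref", "alt", "qual", "filter")


class MalformedHeaderError(ValueError):
    """Raised when a VCF header cannot be interpreted."""


class PedError(ValueError):
    """Raised for unrecoverable PED file problems."""


def normalize_name(raw: str) -> str:
    """Normalize a field identifier: lowercase, non-word runs -> ``_``."""
    return re.sub(r"\W+", "_", raw.strip()).strip("_").lower()


@dataclass(frozen=True)
class FieldDescriptor:
    """One discoverable, queryable field."""

    name: str
    category: str  # core | info | annotation | sample
    value_type: str  # int | float | string | bool
    multiplicity: str = "1"  # VCF Number declaration: 1, A, R, G, '.'
    description: str = ""

    def __post_init__(self) -> None:
        if self.category not in {"core", "info", "annotation", "sample"}:
            raise ValueError(f"bad category {self.category!r}")
        if self.value_type not in {"int", "float", "string", "bool"}:
            raise ValueError(f"bad value_type {self.value_type!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One normalized single-ALT variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    filter: str | None = None
    info: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotationRecord:
    """One transcript-level annotation attached to a variant."""

    variant_key: tuple[str, int, str, str]
    allele: str | None
    fields: dict


@dataclass(frozen=True)
class SampleGenotype:
    variant_key: tuple[str, int, str, str]
    sample: str
    gt: int  # -1 unknown, 0 hom-ref, 1 het, 2 hom-alt
    fields: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PedigreeEntry:
    family: str
    individual: str
    father: str | None
    mother: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    phenotype: int  # 2 affected, 1 unaffected, 0 unknown


@dataclass
class ImportReport:
    n_vcf_records: int = 0
    n_variants: int = 0
    n_annotations: int = 0
    n_samples: int = 0
    n_genotypes: int = 0
    warnings: list = field(default_factory=list)


@dataclass
class VcfSchema:
    """Everything learned from a VCF header, keyed for data-line parsing."""

    descriptors: list
    samples: list
    info_by_id: dict  # raw INFO ID -> FieldDescriptor
    format_by_id: dict  # raw FORMAT ID -> FieldDescriptor
    annotation_fields: list  # normalized names, declaration order
    annotation_source: str | None  # 'ANN' | 'CSQ' | None

    def annotation_descriptors(self) -> list:
        return [d for d in self.descriptors if d.category == "annotation"]


# ---------------------------------------------------------------------------
# header parsing


def _split_meta_pairs(body: str) -> dict:
    """Split the ``<ID=..,Number=..,Description="..">`` body of a meta line,
    honouring quoted commas."""
    pairs: dict[str, str] = {}
    key, buf, in_quotes, state_key = "", [], False, True
    for ch in body:
        if state_key:
            if ch == "=":
                key = "".join(buf).strip()
                buf, state_key = [], False
            else:
                buf.append(ch)
        else:
            if ch == '"':
                in_quotes = not in_quotes
                continue
            if ch == "," and not in_quotes:
                pairs[key] = "".join(buf).strip()
                buf, state_key = [], True
                continue
            buf.append(ch)
    if not state_key and key:
        pairs[key] = "".join(buf).strip()
    return pairs


def _parse_meta_line(line: str) -> tuple[str, dict] | None:
    m = re.match(r"^##(\w+)=<(.*)>\s*$", line)
    if not m:
        return None
    return m.group(1), _split_meta_pairs(m.group(2))


def _annotation_format_fields(description: str) -> list[str]:
    """Extract and normalize the pipe-separated Format clause of an ANN/CSQ
    INFO Description (both the VEP ``Format: a|b|c`` style and the SnpEff
    ``Functional annotations: 'a | b | c'`` style)."""
    m = re.search(r"Format:\s*(.*)$", description, flags=re.IGNORECASE)
    text = m.group(1) if m else description.split(":", 1)[-1]
    text = text.strip().strip("'\"").rstrip(".").strip("'\"")
    names = []
    for part in text.split("|"):
        name = normalize_name(part)
        names.append(ANNOTATION_NAME_ALIASES.get(name, name))
    return [n for n in names if n] or []


def parse_vcf_header(
    header_lines: Sequence[str],
) -> tuple[VcfSchema, list[str]]:
    """Parse ``##`` meta lines plus the final ``#CHROM`` line.

    Returns the schema (field catalogue + sample names) and a list of
    warnings for skipped, unparseable declarations.
    """
    warnings: list[str] = []
    descriptors: list[FieldDescriptor] = [
        FieldDescriptor("chrom", "core", "string", description="Chromosome"),
        FieldDescriptor("pos", "core", "int", description="1-based position"),
        FieldDescriptor("ref", "core", "string", description="Reference allele"),
        FieldDescriptor("alt", "core", "string", description="Alternate allele"),
        FieldDescriptor("qual", "core", "float", description="Variant quality"),
        FieldDescriptor("filter", "core", "string", description="Filter status"),
    ]
    info_by_id: dict[str, FieldDescriptor] = {}
    format_by_id: dict[str, FieldDescriptor] = {}
    annotation_fields: list[str] = []
    annotation_source: str | None = None
    samples: list[str] = []
    saw_chrom_line = False

    for lineno, line in enumerate(header_lines, start=1):
        line = line.rstrip("\n\r")
        if not line:
            continue
        if line.startswith("##"):
            parsed = _parse_meta_line(line)
            if parsed is None:
                continue  # freeform meta (##fileformat=..., ##contig strings)
            kind, pairs = parsed
            if kind not in ("INFO", "FORMAT"):
                continue
            if "ID" not in pairs or "Type" not in pairs:
                warnings.append(
                    f"header line {lineno}: unparseable {kind} declaration skipped"
                )
                continue
            raw_id = pairs["ID"]
            vtype = _TYPE_MAP.get(pairs.get("Type", "String"))
            if vtype is None:
                warnings.append(
                    f"header line {lineno}: unknown Type for {raw_id}, skipped"
                )
                continue
            desc = FieldDescriptor(
                normalize_name(raw_id),
                "info" if kind == "INFO" else "sample",
                vtype,
                pairs.get("Number", "."),
                pairs.get("Description", ""),
            )
            if kind == "INFO":
                if raw_id in ("ANN", "CSQ"):
                    annotation_source = raw_id
                    annotation_fields = _annotation_format_fields(
                        pairs.get("Description", "")
                    )
                    for name in annotation_fields:
                        descriptors.append(
                            FieldDescriptor(
                                name, "annotation", "string", "1",
                                f"{raw_id} field {name}",
                            )
                        )
                    continue
                info_by_id[raw_id] = desc
                descriptors.append(desc)
            else:
                format_by_id[raw_id] = desc
                if raw_id != "GT":  # GT surfaces as the encoded gt code
                    descriptors.append(desc)
        elif line.startswith("#CHROM"):
            cols = line.lstrip("#").split("\t")
            samples = cols[9:]
            saw_chrom_line = True
        else:
            raise MalformedHeaderError(
                f"header line {lineno}: expected '##' or '#CHROM', got {line[:40]!r}"
            )

    if not saw_chrom_line:
        raise MalformedHeaderError("missing #CHROM line")
    descriptors.append(
        FieldDescriptor("gt", "sample", "int", "1", "Encoded genotype code")
    )
    schema = VcfSchema(
        descriptors=descriptors,
        samples=samples,
        info_by_id=info_by_id,
        format_by_id=format_by_id,
        annotation_fields=annotation_fields,
        annotation_source=annotation_source,
    )
    return schema, warnings


# ---------------------------------------------------------------------------
# annotation strings


def _parse_pipe_entries(
    value: str, field_names: Sequence[str]
) -> tuple[list[dict], list[str]]:
    records: list[dict] = []
    warnings: list[str] = []
    for entry in value.split(","):
        parts = entry.split("|")
        if len(parts) < len(field_names):
            warnings.append(
                f"annotation entry has {len(parts)} of {len(field_names)} "
                f"declared fields; padded with missing: {entry[:50]!r}"
            )
            parts = parts + [""] * (len(field_names) - len(parts))
        fields = {
            name: (part.strip() or None)
            for name, part in zip(field_names, parts)
        }
        records.append(fields)
    return records, warnings


def parse_snpeff_ann(
    ann_value: str, ann_fields: Sequence[str]
) -> tuple[list[dict], list[str]]:
    """Split a raw SnpEff ``ANN`` INFO value into per-transcript dicts.

    ``ann_fields`` are the normalized names from the header Format clause.
    Empty pipe positions become missing values; short entries are padded
    with a warning.
    """
    return _parse_pipe_entries(ann_value, ann_fields)


def parse_vep_csq(
    csq_value: str, csq_fields: Sequence[str]
) -> tuple[list[dict], list[str]]:
    """Split a raw VEP ``CSQ`` INFO value; same contract as the ANN parser."""
    return _parse_pipe_entries(csq_value, csq_fields)


# ---------------------------------------------------------------------------
# genotypes

_GT_SPLIT = re.compile(r"[/|]")


def encode_genotype(gt_string: str, alt_index: int = 1) -> int:
    """Encode a raw GT value against ALT allele number ``alt_index``.

    Counts how many called alleles equal ``alt_index``; phased and unphased
    calls are identical, a haploid call is treated as homozygous, any missing
    allele yields -1, and counts are capped at 2 for polyploid calls.
    """
    tokens = _GT_SPLIT.split(gt_string.strip())
    if not tokens or any(t in ("", ".") for t in tokens):
        return -1
    try:
        alleles = [int(t) for t in tokens]
    except ValueError:
        return -1
    if len(alleles) == 1:
        alleles = alleles * 2  # haploid treated as homozygous
    return min(2, sum(1 for a in alleles if a == alt_index))


def _convert_scalar(token: str, value_type: str):
    if token in (".", ""):
        return None
    try:
        if value_type == "int":
            return int(token)
        if value_type == "float":
            return float(token)
    except ValueError:
        return None
    return token


def _parse_info_column(info_col: str, schema: VcfSchema) -> dict:
    """Raw INFO column -> {raw id: raw string value or True for flags}."""
    out: dict[str, object] = {}
    if info_col in (".", ""):
        return out
    for item in info_col.split(";"):
        if not item:
            continue
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
        else:
            out[item] = True
    return out


def _slice_info(
    raw_info: dict, schema: VcfSchema, alt_index: int, n_alts: int
) -> dict:
    """Type and, for Number=A fields, per-ALT slice the raw INFO map.

    Number=R/G fields are kept as unsliced strings (documented limitation).
    """
    info: dict[str, object] = {}
    for raw_id, raw_val in raw_info.items():
        if raw_id in ("ANN", "CSQ"):
            continue
        desc = schema.info_by_id.get(raw_id)
        if desc is None:
            continue  # undeclared INFO key: not queryable, skip
        if desc.value_type == "bool":
            info[desc.name] = True
            continue
        text = str(raw_val)
        if desc.multiplicity == "A":
            parts = text.split(",")
            token = parts[alt_index - 1] if alt_index - 1 < len(parts) else "."
            info[desc.name] = _convert_scalar(token, desc.value_type)
        elif desc.multiplicity == "1":
            info[desc.name] = _convert_scalar(text, desc.value_type)
        else:
            info[desc.name] = text if text != "." else None
    return info


@dataclass
class DecomposedVariant:
    """One per-ALT slice of a raw VCF record."""

    variant: VariantRecord
    genotypes: list  # of SampleGenotype
    annotations: list  # of AnnotationRecord


def decompose_record(
    line: str, schema: VcfSchema
) -> tuple[list[DecomposedVariant], list[str]]:
    """Decompose one VCF data line into one record per ALT allele.

    Per-sample genotype codes are recomputed per ALT (allele-count
    semantics); ``Number=A`` INFO fields are sliced to the matching ALT.
    Annotation entries attach to the decomposed record whose alt equals
    their allele field, falling back to all siblings with a warning.
    """
    warnings: list[str] = []
    cols = line.rstrip("\n\r").split("\t")
    if len(cols) < 8:
        raise ValueError(f"VCF data line has {len(cols)} columns, expected >= 8")
    chrom, pos_s, _id, ref, alt_col, qual_s, filt = cols[:7]
    raw_info = _parse_info_column(cols[7], schema)
    alts = [a for a in alt_col.split(",") if a]
    if alt_col in (".", "") or not alts:
        warnings.append(f"{chrom}:{pos_s}: record without ALT allele skipped")
        return [], warnings

    pos = int(pos_s)
    qual = None if qual_s in (".", "") else float(qual_s)
    filt = None if filt in (".", "") else filt

    fmt_keys = cols[8].split(":") if len(cols) > 8 else []
    sample_cols = cols[9:] if len(cols) > 9 else []

    decomposed: list[DecomposedVariant] = []
    for alt_index, alt in enumerate(alts, start=1):
        info = _slice_info(raw_info, schema, alt_index, len(alts))
        variant = VariantRecord(chrom, pos, ref, alt, qual, filt, info)
        genotypes: list[SampleGenotype] = []
        for sample, raw in zip(schema.samples, sample_cols):
            values = raw.split(":")
            gt_code = -1
            fields: dict[str, object] = {}
            for key, token in zip(fmt_keys, values):
                if key == "GT":
                    gt_code = encode_genotype(token, alt_index)
                else:
                    desc = schema.format_by_id.get(key)
                    if desc is not None:
                        if desc.multiplicity == "1":
                            fields[desc.name] = _convert_scalar(
                                token, desc.value_type
                            )
                        else:
                            fields[desc.name] = token if token != "." else None
            genotypes.append(
                SampleGenotype(variant.key, sample, gt_code, fields)
            )
        decomposed.append(DecomposedVariant(variant, genotypes, []))

    # annotations: allele-matched attachment with attach-to-all fallback
    ann_raw = raw_info.get(schema.annotation_source) if schema.annotation_source else None
    if ann_raw is not None and schema.annotation_fields:
        entries, ann_warnings = _parse_pipe_entries(
            str(ann_raw), schema.annotation_fields
        )
        warnings.extend(f"{chrom}:{pos}: {w}" for w in ann_warnings)
        by_alt = {d.variant.alt: d for d in decomposed}
        for fields in entries:
            allele = fields.get("allele")
            target = by_alt.get(allele) if allele else None
            if target is not None:
                target.annotations.append(
                    AnnotationRecord(target.variant.key, allele, fields)
                )
            else:
                if len(decomposed) > 1 or allele is None:
                    warnings.append(
                        f"{chrom}:{pos}: annotation allele {allele!r} matches "
                        "no ALT; attached to all decomposed records"
                    )
                for d in decomposed:
                    d.annotations.append(
                        AnnotationRecord(d.variant.key, allele, fields)
                    )
    return decomposed, warnings


# ---------------------------------------------------------------------------
# PED


def parse_ped(lines: Iterable[str]) -> list[PedigreeEntry]:
    """Parse a whitespace-delimited 6+ column PED file.

    ``0`` father/mother become None; phenotype ``-9`` maps to unknown (0).
    Raises :class:`PedError` on short lines or duplicate individuals.
    """
    entries: list[PedigreeEntry] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedError(
                f"PED line {lineno}: {len(cols)} columns, expected >= 6"
            )
        family, individual, father, mother, sex_s, pheno_s = cols[:6]
        if individual in seen:
            raise PedError(f"PED line {lineno}: duplicate individual {individual!r}")
        seen.add(individual)
        try:
            sex = int(sex_s)
        except ValueError:
            sex = 0
        try:
            phenotype = int(pheno_s)
        except ValueError:
            phenotype = 0
        if phenotype == -9:
            phenotype = 0
        entries.append(
            PedigreeEntry(
                family,
                individual,
                None if father == "0" else father,
                None if mother == "0" else mother,
                sex if sex in (0, 1, 2) else 0,
                phenotype if phenotype in (0, 1, 2) else 0,
            )
        )
    known = {e.individual for e in entries}
    return entries


def pedigree_warnings(entries: Sequence[PedigreeEntry]) -> list[str]:
    """Dangling father/mother references (warning, not error)."""
    known = {e.individual for e in entries}
    out = []
    for e in entries:
        for role, name in (("father", e.father), ("mother", e.mother)):
            if name is not None and name not in known:
                out.append(
                    f"PED: {role} {name!r} of {e.individual!r} not in file"
                )
    return out


# ---------------------------------------------------------------------------
# import orchestration


def _open_text(path) -> Iterator[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def import_vcf(vcf_path, store, ped_path=None) -> ImportReport:
    """Import an annotated VCF (and optional PED) into ``store``.

    Fully transactional: on any error the store is rolled back and left
    empty.  Pedigree-derived case/control aggregates are materialized per
    variant at import time.
    """
    report = ImportReport()

    pedigree: list[PedigreeEntry] = []
    if ped_path is not None:
        with _open_text(ped_path) as fh:
            pedigree = parse_ped(fh)
        report.warnings.extend(pedigree_warnings(pedigree))

    with _open_text(vcf_path) as fh:
        header_lines: list[str] = []
        first_data_line: str | None = None
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line)
            else:
                first_data_line = line
                break
        schema, header_warnings = parse_vcf_header(header_lines)
        report.warnings.extend(header_warnings)
        report.n_samples = len(schema.samples)

        vcf_samples = set(schema.samples)
        for entry in pedigree:
            if entry.individual not in vcf_samples:
                report.warnings.append(
                    f"PED individual {entry.individual!r} not among VCF samples"
                )

        try:
            store.begin_import(schema, pedigree)
            if first_data_line is not None:
                data_lines = itertools.chain([first_data_line], fh)
            else:
                data_lines = iter(())
            for line in data_lines:
                if not line.strip():
                    continue
                report.n_vcf_records += 1
                decomposed, warnings = decompose_record(line, schema)
                report.warnings.extend(warnings)
                for d in decomposed:
                    store.add_variant(d.variant, d.genotypes, d.annotations)
                    report.n_variants += 1
                    report.n_annotations += len(d.annotations)
                    report.n_genotypes += len(d.genotypes)
            store.finish_import()
        except Exception:
            store.abort_import()
            raise
    return report
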