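"""Deterministic synthetic inputs: annotated VCF/PED/BED/wordset text and
randomized query ASTs.

Everything is driven by a seeded :class:`random.Random`; the same seed
yields byte-identical output.  Expected answers (planted variant keys) are
computed by construction, never by running the query engine.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field

from .vql.ast import (
    Comparison,
    CreateSetOp,
    Drop,
    FieldRef,
    ImportWordset,
    Logical,
    Not,
    SelectStmt,
)

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_snpsift_case",
    "generate_trio",
    "satisfies_mode",
    "random_select",
    "random_statement",
    "GENES",
    "IMPACTS",
]

IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")

CONSEQUENCES = {
    "HIGH": ("stop_gained", "frameshift_variant", "splice_donor_variant"),
    "MODERATE": ("missense_variant", "inframe_deletion"),
    "LOW": ("synonymous_variant", "splice_region_variant"),
    "MODIFIER": ("intron_variant", "upstream_gene_variant", "3_prime_UTR_variant"),
}

GENES = (
    "CFTR", "BRCA1", "BRCA2", "TP53", "EGFR", "KRAS", "MYH7", "DMD",
    "FBN1", "LDLR", "MLH1", "MSH2", "PKD1", "SCN5A", "TTN", "COL1A1",
    "F8", "GBA", "HBB", "HTT", "JAK2", "KCNQ1", "LMNA", "NF1",
    "PAH", "PTEN", "RB1", "RYR1", "SMN1", "VHL",
)

_BASES = "ACGT"

_ANN_HEADER = (
    '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations:'
    " 'Allele | Annotation | Annotation_Impact | Gene_Name | Feature_ID'\">"
)
_CSQ_HEADER = (
    '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations'
    ' from Ensembl VEP. Format: Allele|Consequence|IMPACT|SYMBOL|Feature">'
)


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic annotated cohort VCF."""

    n_variants: int = 100
    n_samples: int = 17
    n_cases: int = 3
    impact_probs: tuple = tuple(zip(IMPACTS, (0.1, 0.3, 0.3, 0.3)))
    multiallelic_fraction: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    annotation_dialect: str = "ANN"  # ANN (SnpEff) | CSQ (VEP)

    def __post_init__(self):
        if self.n_variants < 1 or self.n_samples < 0:
            raise ValueError("n_variants must be >= 1 and n_samples >= 0")
        if not 0 <= self.n_cases <= self.n_samples:
            raise ValueError("n_cases must be between 0 and n_samples")
        if not 0.0 <= self.multiallelic_fraction <= 1.0:
            raise ValueError("multiallelic_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        total = sum(p for _, p in self.impact_probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("impact probabilities must sum to 1")
        if self.annotation_dialect not in ("ANN", "CSQ"):
            raise ValueError("annotation_dialect must be 'ANN' or 'CSQ'")


def _header(samples, dialect: str) -> list:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
        _ANN_HEADER if dialect == "ANN" else _CSQ_HEADER,
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    cols = ["CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols += ["FORMAT", *samples]
    lines.append("#" + "\t".join(cols))
    return lines


def _ann_entry(allele, consequence, impact, gene, transcript, dialect):
    if dialect == "ANN":
        return f"{allele}|{consequence}|{impact}|{gene}|{transcript}"
    return f"{allele}|{consequence}|{impact}|{gene}|{transcript}"


def _pick_impact(rng, impact_probs):
    r = rng.random()
    acc = 0.0
    for impact, p in impact_probs:
        acc += p
        if r < acc:
            return impact
    return impact_probs[-1][0]


def _unique_position(rng, used, chrom):
    while True:
        pos = rng.randint(1_000, 50_000_000)
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            return pos


def _gt_token(code: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}[code]


def _record_line(chrom, pos, ref, alts, qual, info_pairs, gts, dps):
    info = ";".join(f"{k}={v}" for k, v in info_pairs)
    cols = [chrom, str(pos), ".", ref, ",".join(alts), str(qual), "PASS", info]
    if gts:
        cols.append("GT:DP")
        cols += [f"{gt}:{dp}" for gt, dp in zip(gts, dps)]
    return "\t".join(cols)


def generate_cohort(spec: CohortSpec) -> tuple:
    """Synthetic annotated cohort VCF + PED; same seed, same bytes."""
    rng = random.Random(spec.seed)
    samples = [f"S{i:02d}" for i in range(1, spec.n_samples + 1)]
    dialect = spec.annotation_dialect

    used: set = set()
    records = []
    tx_counter = 0
    for _ in range(spec.n_variants):
        chrom = str(rng.randint(1, 22))
        pos = _unique_position(rng, used, chrom)
        ref = rng.choice(_BASES)
        n_alts = 2 if rng.random() < spec.multiallelic_fraction else 1
        alts = rng.sample([b for b in _BASES if b != ref], n_alts)
        qual = round(rng.uniform(10.0, 99.0), 1)
        dp = rng.randint(10, 99)
        afs = [round(rng.uniform(0.01, 0.5), 3) for _ in alts]

        ann_entries = []
        for alt in alts:
            for _ in range(rng.randint(1, 2)):
                tx_counter += 1
                impact = _pick_impact(rng, spec.impact_probs)
                consequence = rng.choice(CONSEQUENCES[impact])
                gene = rng.choice(GENES)
                ann_entries.append(
                    _ann_entry(alt, consequence, impact, gene,
                               f"TX{tx_counter:05d}", dialect)
                )
        info_pairs = [
            ("DP", dp),
            ("AF", ",".join(str(a) for a in afs)),
            (dialect, ",".join(ann_entries)),
        ]

        gts, dps = [], []
        for _ in samples:
            if rng.random() < spec.missing_rate:
                gts.append("./.")
            else:
                a1 = rng.choices(range(n_alts + 1), weights=[6] + [2] * n_alts)[0]
                a2 = rng.choices(range(n_alts + 1), weights=[6] + [2] * n_alts)[0]
                gts.append(f"{min(a1, a2)}/{max(a1, a2)}")
            dps.append(rng.randint(5, 99))
        records.append(((int(chrom), pos),
                        _record_line(chrom, pos, ref, alts, qual,
                                     info_pairs, gts, dps)))

    records.sort(key=lambda r: r[0])
    vcf = "\n".join(_header(samples, dialect) + [r[1] for r in records]) + "\n"

    ped_lines = []
    for i, sample in enumerate(samples):
        phenotype = 2 if i < spec.n_cases else 1
        sex = 1 + i % 2
        ped_lines.append(f"FAM1\t{sample}\t0\t0\t{sex}\t{phenotype}")
    ped = "\n".join(ped_lines) + "\n"
    return vcf, ped


# ---------------------------------------------------------------------------
# the cohort worked example: 17 samples, 3 affected, one planted variant


def generate_snpsift_case(
    seed: int = 20210903, n_decoys: int = 220, dialect: str = "ANN",
) -> tuple:
    """Cohort fixture with exactly one variant passing
    ``case_count_hom=3 AND control_count_hom=0 AND impact IN ('HIGH',
    'MODERATE')``: a homozygous-in-cases CFTR stop gain.  Every decoy
    violates at least one clause by construction.  Returns
    ``(vcf_text, ped_text, expected_key)``.
    """
    rng = random.Random(seed)
    cases = [f"Case{i}" for i in range(1, 4)]
    controls = [f"Ctrl{i}" for i in range(1, 15)]
    samples = cases + controls

    used: set = set()
    records = []
    tx = 0

    def add_record(chrom, pos, ref, alt, impacts, gene, case_gts, ctrl_gts):
        nonlocal tx
        entries = []
        for impact in impacts:
            tx += 1
            consequence = rng.choice(CONSEQUENCES[impact])
            entries.append(
                _ann_entry(alt, consequence, impact, gene, f"TX{tx:05d}", dialect)
            )
        info_pairs = [("DP", rng.randint(30, 99)),
                      ("AF", round(rng.uniform(0.01, 0.3), 3)),
                      (dialect, ",".join(entries))]
        gts = case_gts + ctrl_gts
        dps = [rng.randint(20, 99) for _ in samples]
        qual = round(rng.uniform(40.0, 99.0), 1)
        records.append(((int(chrom), pos),
                        _record_line(chrom, pos, ref, alt and [alt], qual,
                                     info_pairs, gts, dps)))

    # the planted CFTR G542* analogue: HIGH impact, hom in all three cases,
    # never hom in controls
    planted_chrom, planted_pos = "7", 117_199_646
    used.add((planted_chrom, planted_pos))
    tx += 1
    planted_entries = [
        f"T|stop_gained|HIGH|CFTR|TX{tx:05d}" if dialect == "ANN"
        else f"T|stop_gained|HIGH|CFTR|TX{tx:05d}"
    ]
    info_pairs = [("DP", 72), ("AF", 0.12), (dialect, ",".join(planted_entries))]
    planted_gts = ["1/1"] * 3 + [rng.choice(["0/0", "0/1"]) for _ in controls]
    records.append(((7, planted_pos),
                    _record_line(planted_chrom, planted_pos, "G", ["T"], 88.0,
                                 info_pairs, planted_gts,
                                 [rng.randint(20, 99) for _ in samples])))
    expected_key = (planted_chrom, planted_pos, "G", "T")

    decoy_kinds = ["case", "control", "impact"]
    for i in range(n_decoys):
        kind = decoy_kinds[i % 3]
        chrom = str(rng.randint(1, 22))
        pos = _unique_position(rng, used, chrom)
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        gene = rng.choice(GENES)
        if kind == "case":
            # fails case_count_hom=3: at most two cases homozygous
            n_hom = rng.randint(0, 2)
            case_gts = ["1/1"] * n_hom + [
                rng.choice(["0/0", "0/1"]) for _ in range(3 - n_hom)
            ]
            ctrl_gts = [rng.choice(["0/0", "0/1", "1/1"]) for _ in controls]
            impacts = [rng.choice(IMPACTS) for _ in range(rng.randint(1, 2))]
        elif kind == "control":
            # fails control_count_hom=0: at least one control homozygous
            case_gts = ["1/1"] * 3
            n_hom = rng.randint(1, 3)
            ctrl_gts = ["1/1"] * n_hom + [
                rng.choice(["0/0", "0/1"]) for _ in range(len(controls) - n_hom)
            ]
            impacts = [rng.choice(IMPACTS) for _ in range(rng.randint(1, 2))]
        else:
            # fails the impact IN clause: only LOW/MODIFIER annotations
            case_gts = ["1/1"] * 3
            ctrl_gts = [rng.choice(["0/0", "0/1"]) for _ in controls]
            impacts = [rng.choice(("LOW", "MODIFIER"))
                       for _ in range(rng.randint(1, 2))]
        add_record(chrom, pos, ref, alt, impacts, gene, case_gts, ctrl_gts)

    records.sort(key=lambda r: r[0])
    vcf = "\n".join(_header(samples, dialect) + [r[1] for r in records]) + "\n"

    ped_lines = [f"FAM1\t{s}\t0\t0\t1\t2" for s in cases]
    ped_lines += [f"FAM1\t{s}\t0\t0\t2\t1" for s in controls]
    ped = "\n".join(ped_lines) + "\n"
    return vcf, ped, expected_key


# ---------------------------------------------------------------------------
# trio transmission fixtures


def satisfies_mode(mode: str, child: int, father: int, mother: int) -> bool:
    """Ground-truth transmission rule on genotype codes (no engine code)."""
    if mode == "denovo":
        return child in (1, 2) and father == 0 and mother == 0
    if mode == "autosomal_recessive":
        return child == 2 and father == 1 and mother == 1
    if mode == "dominant":
        return child in (1, 2) and (father in (1, 2) or mother in (1, 2))
    raise ValueError(f"unknown mode {mode!r}")


def _mode_combos(mode: str):
    codes = (-1, 0, 1, 2)
    satisfying, failing = [], []
    for c in codes:
        for f in codes:
            for m in codes:
                (satisfying if satisfies_mode(mode, c, f, m) else failing).append(
                    (c, f, m)
                )
    return satisfying, failing


def generate_trio(
    mode: str, seed: int = 11, n_planted: int = 5, n_decoys: int = 60,
    dialect: str = "ANN",
) -> tuple:
    """Trio VCF + PED with ``n_planted`` variants satisfying exactly
    ``mode`` plus decoys that fail it.  Returns
    ``(vcf_text, ped_text, expected_keys)``.

    A dominant planting never doubles as autosomal-recessive; the
    recessive genotype pattern (child hom, parents het) inherently also
    matches the dominant rule, which is acknowledged rather than avoided.
    """
    rng = random.Random(seed)
    samples = ["CHILD", "FATHER", "MOTHER"]
    satisfying, failing = _mode_combos(mode)
    if mode == "dominant":
        satisfying = [
            combo for combo in satisfying
            if not satisfies_mode("autosomal_recessive", *combo)
        ]

    used: set = set()
    records = []
    expected_keys = []
    tx = 0
    plan = [True] * n_planted + [False] * n_decoys
    rng.shuffle(plan)
    for is_planted in plan:
        chrom = str(rng.randint(1, 22))
        pos = _unique_position(rng, used, chrom)
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        combo = rng.choice(satisfying if is_planted else failing)
        tx += 1
        impact = rng.choice(IMPACTS)
        entry = _ann_entry(alt, rng.choice(CONSEQUENCES[impact]), impact,
                           rng.choice(GENES), f"TX{tx:05d}", dialect)
        info_pairs = [("DP", rng.randint(20, 99)),
                      ("AF", round(rng.uniform(0.01, 0.4), 3)),
                      (dialect, entry)]
        gts = [_gt_token(code) for code in combo]
        dps = [rng.randint(10, 99) for _ in samples]
        qual = round(rng.uniform(30.0, 99.0), 1)
        if is_planted:
            expected_keys.append((chrom, pos, ref, alt))
        records.append(((int(chrom), pos),
                        _record_line(chrom, pos, ref, [alt], qual,
                                     info_pairs, gts, dps)))

    records.sort(key=lambda r: r[0])
    vcf = "\n".join(_header(samples, dialect) + [r[1] for r in records]) + "\n"
    ped = (
        "FAM1\tCHILD\tFATHER\tMOTHER\t1\t2\n"
        "FAM1\tFATHER\t0\t0\t1\t1\n"
        "FAM1\tMOTHER\t0\t0\t2\t1\n"
    )
    expected_keys.sort(key=lambda k: (int(k[0]), k[1]))
    return vcf, ped, expected_keys


# ---------------------------------------------------------------------------
# randomized queries (for round-trip and oracle-equivalence sweeps)

_REGEXES = ("^CF", "TR", "variant$", "^B", "stop", "A")
_CHROMS = tuple(str(c) for c in range(1, 23))


def _field_pool(samples, wordsets):
    """(FieldRef, value_type, value pool) triples matching the cohort
    fixture's catalogue."""
    pool = [
        (FieldRef("chr"), "string", _CHROMS),
        (FieldRef("chrom"), "string", _CHROMS),
        (FieldRef("pos"), "int", tuple(range(1_000, 50_000_000, 999_983))),
        (FieldRef("ref"), "string", tuple(_BASES)),
        (FieldRef("alt"), "string", tuple(_BASES)),
        (FieldRef("qual"), "float", tuple(round(q, 1) for q in
                                          (10.0, 25.5, 40.0, 60.0, 90.0))),
        (FieldRef("dp"), "int", (10, 30, 50, 80)),
        (FieldRef("depth"), "int", (10, 30, 50, 80)),
        (FieldRef("af"), "float", (0.05, 0.1, 0.25, 0.4)),
        (FieldRef("count_hom"), "int", (0, 1, 2, 3, 5)),
        (FieldRef("count_het"), "int", (0, 1, 2, 3, 5)),
        (FieldRef("count_var"), "int", (0, 1, 3, 8)),
        (FieldRef("case_count_hom"), "int", (0, 1, 2, 3)),
        (FieldRef("control_count_hom"), "int", (0, 1, 2)),
        (FieldRef("gene", "ann"), "string", GENES[:8]),
        (FieldRef("gene"), "string", GENES[:8]),
        (FieldRef("impact", "ann"), "string", IMPACTS),
        (FieldRef("impact"), "string", IMPACTS),
        (FieldRef("consequence", "ann"), "string",
         tuple(c for group in CONSEQUENCES.values() for c in group)),
        (FieldRef("transcript", "ann"), "string", ("TX00001", "TX00010")),
    ]
    for sample in samples:
        pool.append((FieldRef("gt", "sample", sample), "int", (-1, 0, 1, 2)))
        pool.append((FieldRef("dp", "sample", sample), "int", (10, 30, 60)))
    return pool


def _random_leaf(rng, pool, wordsets):
    ref, vtype, values = rng.choice(pool)
    if vtype == "string":
        ops = ["=", "=", "!=", "IN", "NOT IN", "~", "IS NULL", "IS NOT NULL"]
        if wordsets:
            ops.append("IN WORDSET")
    else:
        ops = ["=", "!=", "<", "<=", ">", ">=", "IN", "NOT IN"]
    op = rng.choice(ops)
    if op in ("IS NULL", "IS NOT NULL"):
        return Comparison(ref, op)
    if op == "~":
        return Comparison(ref, "~", rng.choice(_REGEXES))
    if op == "IN WORDSET":
        return Comparison(ref, op, rng.choice(list(wordsets)))
    if op in ("IN", "NOT IN"):
        k = rng.randint(1, min(3, len(values)))
        return Comparison(ref, op, tuple(rng.sample(list(values), k)))
    return Comparison(ref, op, rng.choice(values))


def _random_filter(rng, pool, wordsets, depth: int):
    if depth <= 0 or rng.random() < 0.45:
        node = _random_leaf(rng, pool, wordsets)
    else:
        n = rng.randint(2, 3)
        children = tuple(
            _random_filter(rng, pool, wordsets, depth - 1) for _ in range(n)
        )
        node = Logical(rng.choice(("AND", "OR")), children)
    if rng.random() < 0.15:
        node = Not(node)
    return node


def random_select(
    rng, samples=("S01", "S02"), wordsets=(), selections=("variants",),
    max_depth: int = 2,
) -> SelectStmt:
    """A random, type-correct SELECT over the cohort fixture's schema."""
    pool = _field_pool(samples, wordsets)
    n_fields = rng.randint(1, 4)
    seen, select_list = set(), []
    for _ in range(n_fields):
        ref = rng.choice(pool)[0]
        if ref not in seen:
            seen.add(ref)
            select_list.append(ref)
    filt = None
    if rng.random() < 0.9:
        filt = _random_filter(rng, pool, wordsets, max_depth)
    order_by = ()
    if rng.random() < 0.5:
        n_keys = rng.randint(1, 2)
        refs = rng.sample([p[0] for p in pool], n_keys)
        order_by = tuple((r, rng.choice(("ASC", "DESC"))) for r in refs)
    limit = offset = None
    if rng.random() < 0.3:
        limit = rng.randint(1, 50)
        if rng.random() < 0.4:
            offset = rng.randint(0, 10)
    return SelectStmt(tuple(select_list), rng.choice(list(selections)),
                      filt, order_by, limit, offset)


def random_statement(rng, **kwargs):
    """A random statement of any kind (round-trip fodder)."""
    r = rng.random()
    if r < 0.7:
        return random_select(rng, **kwargs)
    if r < 0.8:
        return CreateSetOp(
            f"sel_{rng.randint(0, 99)}",
            rng.choice(("variants", "rare", "coding")),
            rng.choice(("&", "|", "-")),
            rng.choice(("variants", "damaging")),
        )
    if r < 0.9:
        return Drop(rng.choice(("selection", "wordset")),
                    f"name_{rng.randint(0, 99)}")
    return ImportWordset(f"genes_{rng.randint(0, 9)}.txt",
                         f"ws_{rng.randint(0, 99)}")
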