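"""Test-only oracles, independent of the package's query machinery."""

from __future__ import annotations


def parse_vcf_text(vcf_text: str):
    """Minimal line-level VCF reader for oracle purposes: yields
    (chrom, pos, ref, alts, info_dict, sample_gt_strings, samples)."""
    samples = []
    for line in vcf_text.splitlines():
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#CHROM"):
            samples = line.split("\t")[9:]
            continue
        cols = line.split("\t")
        info = {}
        for item in cols[7].split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                info[k] = v
            else:
                info[item] = True
        fmt_keys = cols[8].split(":") if len(cols) > 8 else []
        gts = []
        for raw in cols[9:]:
            values = dict(zip(fmt_keys, raw.split(":")))
            gts.append(values.get("GT", "./."))
        yield cols[0], int(cols[1]), cols[3], cols[4].split(","), info, gts, samples


def gt_is_hom_alt(gt: str) -> bool:
    alleles = gt.replace("|", "/").split("/")
    return all(a == "1" for a in alleles) and len(alleles) >= 1 and "." not in gt


def snpsift_cohort_filter(vcf_text: str, case_samples, control_samples):
    """Independent per-record filter mimicking the SnpSift cohort
    expression ``(Cases[0]=3) & (Controls[0]=0) &
    ((ANN[*].IMPACT='HIGH')|(ANN[*].IMPACT='MODERATE'))``.

    Operates on the raw VCF text, one record at a time, with no use of the
    package's store, parser or engine.  Returns the set of passing
    (chrom, pos, ref, alt) keys (single-ALT records assumed).
    """
    passing = set()
    for chrom, pos, ref, alts, info, gts, samples in parse_vcf_text(vcf_text):
        by_sample = dict(zip(samples, gts))
        n_case_hom = sum(gt_is_hom_alt(by_sample[s]) for s in case_samples)
        n_ctrl_hom = sum(gt_is_hom_alt(by_sample[s]) for s in control_samples)
        ann = str(info.get("ANN", info.get("CSQ", "")))
        impacts = {entry.split("|")[2] for entry in ann.split(",") if entry}
        if (
            n_case_hom == 3
            and n_ctrl_hom == 0
            and impacts & {"HIGH", "MODERATE"}
        ):
            for alt in alts:
                passing.add((chrom, pos, ref, alt))
    return passing


def brute_force_gt_code(gt: str, alt_index: int) -> int:
    """Independent allele-count genotype encoding oracle."""
    alleles = gt.replace("|", "/").split("/")
    if any(a in (".", "") for a in alleles):
        return -1
    try:
        nums = [int(a) for a in alleles]
    except ValueError:
        return -1
    if len(nums) == 1:
        nums = nums * 2
    return min(2, sum(1 for a in nums if a == alt_index))
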