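"""Independent brute-force oracles for cross-checking the implementation.

Everything here is deliberately written from first principles — plain
text parsing and rule-by-rule loops — and shares no code path with the
package (no pysam, no engine imports), so agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import math
from math import comb

# --- consequence precedence table (independent copy) -----------------------

_LOF = {
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
    "transcript_ablation",
}
_INFRAME = {"inframe_insertion", "inframe_deletion", "stop_lost"}

_MONO_LIKE = {
    "monoallelic",
    "hemizygous",
    "x_linked_dominant",
    "x_linked_over_dominance",
    "imprinted",
    "mosaic",
}
_UNSUPPORTED = {"digenic", "mitochondrial", "uncertain"}

_ALLOWED = {
    "loss_of_function": {"lof", "missense", "inframe", "splice_region"},
    "all_missense_in_frame": {"missense", "inframe"},
    "activating": {"missense", "inframe"},
    "dominant_negative": {"missense", "inframe"},
    "uncertain": {"lof", "missense", "inframe", "splice_region"},
    "utr_mutation": set(),
    "cis_regulatory": set(),
    "increased_gene_dosage": set(),
}


def classify(terms):
    terms = set(terms)
    if terms & _LOF:
        return "lof"
    if "missense_variant" in terms:
        return "missense"
    if terms & _INFRAME:
        return "inframe"
    if "splice_region_variant" in terms:
        return "splice_region"
    return "other"


# --- plain-text VCF parsing -------------------------------------------------


def parse_vcf_text(text: str):
    """Return (csq_fields, samples, records) from raw VCF text."""
    csq_fields, samples, records = None, None, []
    for line in text.splitlines():
        if line.startswith("##INFO=<ID=CSQ"):
            fmt = line.split("Format: ")[1].rstrip('">')
            csq_fields = fmt.split("|")
        elif line.startswith("#CHROM"):
            samples = line.rstrip("\n").split("\t")[9:]
        elif line and not line.startswith("#"):
            f = line.rstrip("\n").split("\t")
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, True) for kv in f[7].split(";")
            )
            fmt_keys = f[8].split(":")
            calls = {}
            for s, cell in zip(samples, f[9:]):
                calls[s] = dict(zip(fmt_keys, cell.split(":")))
            records.append(
                {
                    "chrom": f[0],
                    "pos": int(f[1]),
                    "ref": f[3],
                    "alt": f[4],
                    "mq": float(info["MQ"]) if "MQ" in info else None,
                    "csq": [
                        dict(zip(csq_fields, block.split("|")))
                        for block in str(info.get("CSQ", "")).split(",")
                        if block
                    ],
                    "calls": calls,
                }
            )
    return csq_fields, samples, records


def zygosity_of(gt: str) -> str:
    alleles = gt.replace("|", "/").split("/")
    if any(a == "." for a in alleles):
        return "no_call"
    if len(alleles) == 1:
        return "hemi" if alleles[0] == "1" else "hom_ref"
    vals = set(alleles)
    if vals == {"0"}:
        return "hom_ref"
    if vals == {"1"}:
        return "hom_alt"
    return "het"


def call_survives_quality(call: dict, mq, gq_min=13, dp_min=5, ratio_min=0.2, mq_min=13) -> bool:
    if "GQ" in call and call["GQ"] != "." and float(call["GQ"]) < gq_min:
        return False
    if "DP" in call and call["DP"] != "." and int(call["DP"]) < dp_min:
        return False
    if "AD" in call and "DP" in call and call["AD"] != ".":
        dp = int(call["DP"])
        alt = int(call["AD"].split(",")[1])
        if dp > 0 and alt / dp < ratio_min:
            return False
    if mq is not None and mq < mq_min:
        return False
    return True


def max_af_of(block: dict) -> float:
    afs = [
        float(v)
        for k, v in block.items()
        if v and (k == "AF" or k.endswith("_AF"))
    ]
    return max(afs) if afs else 0.0


def oracle_filter(
    vcf_text: str,
    panel_rows,
    sex: dict | None = None,
    maf_mono: float = 1e-4,
    maf_bi: float = 5e-3,
    canonical_only: bool = True,
):
    """Re-derive (sample, thread) -> (satisfied, qualifying variant keys).

    ``panel_rows`` is a list of dicts with keys gene, disease,
    confidence, requirement, consequence — reportable rows only.  A
    variant qualifies for a thread when some transcript annotation of its
    gene is canonical (if required), of an allowed consequence class, and
    has max AF strictly under the thread's threshold (0 means unseen
    only; the thresholds here are always positive).
    """
    sex = sex or {}
    _, samples, records = parse_vcf_text(vcf_text)
    hits: dict[tuple, dict] = {}
    for rec in records:
        by_gene: dict[str, list[dict]] = {}
        for block in rec["csq"]:
            by_gene.setdefault(block["SYMBOL"], []).append(block)
        for row in panel_rows:
            gene = row["gene"]
            if gene not in by_gene:
                continue
            threshold = maf_bi if row["requirement"] == "biallelic" else maf_mono
            ok = False
            for block in by_gene[gene]:
                if canonical_only and block.get("CANONICAL") != "YES":
                    continue
                cls = classify(block["Consequence"].split("&"))
                if cls not in _ALLOWED[row["consequence"]]:
                    continue
                af = max_af_of(block)
                if (af < threshold) if threshold > 0 else (af == 0.0):
                    ok = True
            if not ok:
                continue
            for s in samples:
                call = rec["calls"][s]
                zyg = zygosity_of(call["GT"])
                if zyg in ("hom_ref", "no_call"):
                    continue
                if not call_survives_quality(call, rec["mq"]):
                    continue
                key = (s, gene, row["disease"], row["requirement"], row["consequence"])
                hits.setdefault(key, {"zygs": [], "sites": set()})
                hits[key]["zygs"].append(zyg)
                hits[key]["sites"].add((rec["chrom"], rec["pos"], rec["ref"], rec["alt"], zyg))
    out = {}
    for key, h in hits.items():
        sample, gene, disease, req, mc = key
        zygs = h["zygs"]
        n_het_sites = len({s for s in h["sites"] if s[4] == "het"})
        if req in _UNSUPPORTED:
            satisfied = False
        elif req == "biallelic":
            satisfied = "hom_alt" in zygs or n_het_sites >= 2
        elif req == "hemizygous":
            satisfied = (
                "hemi" in zygs
                or "hom_alt" in zygs
                or ("het" in zygs and sex.get(sample, "unknown") in ("female", "unknown"))
            )
        elif req in _MONO_LIKE:
            satisfied = any(z in ("het", "hom_alt", "hemi") for z in zygs)
        else:
            satisfied = False
        out[key] = {
            "satisfied": satisfied,
            "variants": frozenset((c, p, r, a) for c, p, r, a, _ in h["sites"]),
        }
    return out


# --- exact hypergeometric enumeration for the Fisher test -------------------


def fisher_p_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by summing hypergeometric probabilities <= observed."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c

    def p_of(k: int) -> float:
        return comb(c1, k) * comb(n - c1, r1 - k) / comb(n, r1)

    p_obs = p_of(a)
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    return sum(p_of(k) for k in range(lo, hi + 1) if p_of(k) <= p_obs * (1 + 1e-9))


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)
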