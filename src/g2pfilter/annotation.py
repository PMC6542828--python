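"""Parsing and classification of VEP-style CSQ transcript annotations.

The variant annotator writes one pipe-delimited block per (alternate
allele, overlapping transcript) pair into the ``CSQ`` INFO field, with the
field order declared once in the VCF header::

    ##INFO=<ID=CSQ,...,Description="Consequence annotations ... Format: Allele|Consequence|...">

This module reads that declaration, splits record values into
:class:`TranscriptConsequence` objects, classifies Sequence Ontology
consequence terms into the coarse classes used for filtering, and exposes
the per-mechanism allowed-class table and the maximum population allele
frequency across reference cohorts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import FormatError, ValidationError
from .vocab import CLASS_SEVERITY, ConsequenceClass, MutationConsequence

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptConsequence",
    "parse_csq_format",
    "parse_csq",
    "classify_consequence",
    "allowed_classes",
    "max_population_af",
    "LOF_TERMS",
]

#: Sequence Ontology terms treated as loss-of-function.  Not a universal
#: constant — override via :func:`classify_consequence`'s ``lof_terms``.
LOF_TERMS = frozenset(
    {
        "stop_gained",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "start_lost",
        "transcript_ablation",
    }
)

_INFRAME_TERMS = frozenset({"inframe_insertion", "inframe_deletion", "stop_lost"})

#: CSQ subfield names recognised as population allele-frequency sources.
#: Any field named ``AF`` or ending in ``_AF`` is accepted, so pooled and
#: sub-population frequencies from any annotated cohort are picked up.
_AF_FIELD = re.compile(r"(^AF$)|(_AF$)", re.IGNORECASE)

_PREDICTION_RE = re.compile(r"^\s*([A-Za-z_ ]+?)\s*(?:\(([0-9.eE+-]+)\))?\s*$")


@dataclass(frozen=True)
class TranscriptConsequence:
    """One alternate-allele-on-transcript annotation block."""

    allele: str
    gene_symbol: str
    transcript_id: str
    so_terms: tuple[str, ...]
    is_canonical: bool = False
    sift_prediction: str | None = None  # "deleterious" / "tolerated"
    sift_score: float | None = None
    polyphen_prediction: str | None = None  # "probably_damaging" / "possibly_damaging" / "benign"
    polyphen_score: float | None = None
    cadd_phred: float | None = None
    population_afs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.so_terms:
            raise ValidationError("TranscriptConsequence requires at least one SO term")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValidationError(f"CADD Phred score must be >= 0, got {self.cadd_phred}")
        for src, af in self.population_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValidationError(f"allele frequency {src}={af} outside [0, 1]")

    @property
    def sift_deleterious(self) -> bool | None:
        if self.sift_prediction is None:
            return None
        return self.sift_prediction.startswith("deleterious")

    @property
    def polyphen_damaging(self) -> bool | None:
        if self.polyphen_prediction is None:
            return None
        return self.polyphen_prediction.endswith("damaging")


def parse_csq_format(header_description: str) -> list[str]:
    """Extract the pipe-delimited CSQ subfield order from the header description."""
    m = re.search(r"Format:\s*([^\"]+)", header_description)
    if not m:
        raise FormatError(
            f"CSQ header description lacks a 'Format: ...' clause: {header_description!r}"
        )
    return [f.strip() for f in m.group(1).strip().strip('"').split("|")]


def _parse_prediction(cell: str) -> tuple[str | None, float | None]:
    """Split a 'prediction(score)' cell as written for SIFT/PolyPhen."""
    m = _PREDICTION_RE.match(cell)
    if not m:
        return None, None
    pred = m.group(1).strip().lower().replace(" ", "_")
    score = float(m.group(2)) if m.group(2) is not None else None
    return pred, score


def _block_to_annotation(
    fields: Sequence[str], values: Sequence[str], where: str
) -> TranscriptConsequence:
    if len(values) != len(fields):
        raise FormatError(
            f"{where}: CSQ block has {len(values)} subfields, header declares {len(fields)}"
        )
    d = {f: v for f, v in zip(fields, values) if v != ""}
    afs: dict[str, float] = {}
    for key, raw in d.items():
        if _AF_FIELD.search(key):
            try:
                afs[key] = float(raw)
            except ValueError:
                raise FormatError(f"{where}: non-numeric allele frequency {key}={raw!r}") from None
    sift_pred, sift_score = _parse_prediction(d["SIFT"]) if "SIFT" in d else (None, None)
    pp_pred, pp_score = _parse_prediction(d["PolyPhen"]) if "PolyPhen" in d else (None, None)
    cadd = d.get("CADD_PHRED") or d.get("CADD_phred")
    return TranscriptConsequence(
        allele=d.get("Allele", ""),
        gene_symbol=d.get("SYMBOL") or d.get("Gene", ""),
        transcript_id=d.get("Feature", ""),
        so_terms=tuple(t for t in d.get("Consequence", "").split("&") if t),
        is_canonical=d.get("CANONICAL", "") in ("YES", "1"),
        sift_prediction=sift_pred,
        sift_score=sift_score,
        polyphen_prediction=pp_pred,
        polyphen_score=pp_score,
        cadd_phred=float(cadd) if cadd else None,
        population_afs=afs,
    )


def parse_csq(
    header_description: str | Sequence[str],
    record_csq_value: "str | Sequence[str] | None",
    where: str = "record",
) -> list[TranscriptConsequence]:
    """Parse one record's CSQ value into transcript annotations.

    ``header_description`` may be the raw header Description text or an
    already-split field list.  ``record_csq_value`` may be the raw
    comma-joined INFO string or a pre-split block sequence (as VCF
    readers hand back ``Number=.`` fields).  An absent CSQ value yields
    an empty list (logged); a field-count mismatch between header and
    record raises :class:`~g2pfilter.errors.FormatError` naming the record.
    """
    fields = (
        list(header_description)
        if not isinstance(header_description, str)
        else parse_csq_format(header_description)
    )
    if not record_csq_value:
        logger.debug("%s: no CSQ annotation present", where)
        return []
    blocks = (
        record_csq_value.split(",")
        if isinstance(record_csq_value, str)
        else list(record_csq_value)
    )
    return [_block_to_annotation(fields, block.split("|"), where) for block in blocks]


def classify_consequence(
    so_terms: Iterable[str], lof_terms: frozenset[str] = LOF_TERMS
) -> ConsequenceClass:
    """Map Sequence Ontology terms onto a coarse consequence class.

    Most-severe-wins precedence: loss-of-function beats missense beats
    in-frame beats splice-region; unrecognised terms fall through to
    ``other``.  The result is independent of term order.
    """
    terms = set(so_terms)
    if not terms:
        raise ValidationError("classify_consequence requires a non-empty term list")
    if terms & lof_terms:
        return ConsequenceClass.LOF
    if "missense_variant" in terms:
        return ConsequenceClass.MISSENSE
    if terms & _INFRAME_TERMS:
        return ConsequenceClass.INFRAME
    if "splice_region_variant" in terms:
        return ConsequenceClass.SPLICE_REGION
    return ConsequenceClass.OTHER


#: Consequence classes that can support each mutation-consequence mechanism.
#: Loss-of-function genes also admit predicted-deleterious missense and
#: in-frame changes; purely non-coding mechanisms (UTR, cis-regulatory,
#: dosage) are not detectable from coding consequences and map to the
#: empty set, which the engine reports as unsupported.
_ALLOWED: dict[MutationConsequence, frozenset[ConsequenceClass]] = {
    MutationConsequence.LOSS_OF_FUNCTION: frozenset(
        {
            ConsequenceClass.LOF,
            ConsequenceClass.MISSENSE,
            ConsequenceClass.INFRAME,
            ConsequenceClass.SPLICE_REGION,
        }
    ),
    MutationConsequence.ALL_MISSENSE_IN_FRAME: frozenset(
        {ConsequenceClass.MISSENSE, ConsequenceClass.INFRAME}
    ),
    MutationConsequence.ACTIVATING: frozenset(
        {ConsequenceClass.MISSENSE, ConsequenceClass.INFRAME}
    ),
    MutationConsequence.DOMINANT_NEGATIVE: frozenset(
        {ConsequenceClass.MISSENSE, ConsequenceClass.INFRAME}
    ),
    MutationConsequence.UNCERTAIN: frozenset(
        {
            ConsequenceClass.LOF,
            ConsequenceClass.MISSENSE,
            ConsequenceClass.INFRAME,
            ConsequenceClass.SPLICE_REGION,
        }
    ),
    MutationConsequence.UTR_MUTATION: frozenset(),
    MutationConsequence.CIS_REGULATORY: frozenset(),
    MutationConsequence.INCREASED_GENE_DOSAGE: frozenset(),
}


def allowed_classes(
    mc: MutationConsequence | str,
    overrides: Mapping[MutationConsequence, frozenset[ConsequenceClass]] | None = None,
) -> frozenset[ConsequenceClass]:
    """Consequence classes accepted for a mutation-consequence mechanism."""
    mc = MutationConsequence.parse(mc)
    table = dict(_ALLOWED)
    if overrides:
        table.update(overrides)
    return table[mc]


def max_population_af(tc: TranscriptConsequence) -> float:
    """Maximum allele frequency across all populated reference sources.

    An allele unseen in every control database has frequency 0 — the
    strongest possible rarity evidence.
    """
    if not tc.population_afs:
        return 0.0
    return max(tc.population_afs.values())


def severity_rank(cls: ConsequenceClass) -> int:
    """Lower is more severe; used for deterministic winner selection."""
    return CLASS_SEVERITY[cls]
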