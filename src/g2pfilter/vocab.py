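"""Controlled vocabularies for gene-panel entries and variant annotations.

Gene-to-disease panel entries carry three curated vocabulary fields:

* confidence — how well established the gene-disease association is
  (``confirmed`` and ``probable`` are reportable for diagnosis,
  ``possible`` is not; ``both_rd_and_if`` marks associations relevant both
  to the referred disease and as an incidental finding);
* allelic requirement — the genotype configuration required at the locus
  (monoallelic, biallelic, hemizygous, ...);
* mutation consequence — the mechanism class of pathogenic variation
  (loss of function, activating, all missense/in-frame, ...).

Parsing is case-insensitive and tolerant of the punctuation variants seen
in public panel exports ("loss-of-function", "X-linked dominant", ...).
Unknown strings are rejected with :class:`~g2pfilter.errors.ValidationError`.
"""

from __future__ import annotations

import enum
import re

from .errors import ValidationError

__all__ = [
    "Confidence",
    "AllelicRequirement",
    "MutationConsequence",
    "ConsequenceClass",
    "Zygosity",
]


def _normalise(value: str) -> str:
    """Lower-case and collapse punctuation so vocabulary variants compare equal."""
    s = value.strip().lower()
    s = re.sub(r"[\s/\-,]+", "_", s)
    s = re.sub(r"_+", "_", s)
    return s.strip("_")


class _VocabEnum(str, enum.Enum):
    """String enum with tolerant, alias-aware parsing."""

    @classmethod
    def _aliases(cls) -> dict[str, str]:
        return {}

    @classmethod
    def parse(cls, value: "str | _VocabEnum"):
        if isinstance(value, cls):
            return value
        key = _normalise(str(value))
        key = cls._aliases().get(key, key)
        try:
            return cls(key)
        except ValueError:
            raise ValidationError(
                f"unknown {cls.__name__} value: {value!r} "
                f"(accepted: {', '.join(m.value for m in cls)})"
            ) from None


class Confidence(_VocabEnum):
    CONFIRMED = "confirmed"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    BOTH_RD_AND_IF = "both_rd_and_if"

    @classmethod
    def _aliases(cls):
        return {
            "rd_and_if": "both_rd_and_if",
            "both_rd_if": "both_rd_and_if",
            "definitive": "confirmed",
            "strong": "probable",
            "limited": "possible",
        }

    @property
    def reportable(self) -> bool:
        """Confirmed, probable and RD+IF entries are reportable; possible is not."""
        return self is not Confidence.POSSIBLE


class AllelicRequirement(_VocabEnum):
    MONOALLELIC = "monoallelic"
    BIALLELIC = "biallelic"
    HEMIZYGOUS = "hemizygous"
    X_LINKED_DOMINANT = "x_linked_dominant"
    X_LINKED_OVER_DOMINANCE = "x_linked_over_dominance"
    IMPRINTED = "imprinted"
    MOSAIC = "mosaic"
    MITOCHONDRIAL = "mitochondrial"
    DIGENIC = "digenic"
    UNCERTAIN = "uncertain"

    @classmethod
    def _aliases(cls):
        return {
            "x_linked_over_dominant": "x_linked_over_dominance",
            "monoallelic_autosomal": "monoallelic",
            "biallelic_autosomal": "biallelic",
            "unknown": "uncertain",
        }


#: Requirements where a single altered allele suffices; these share the
#: stricter monoallelic MAF threshold in the filter engine.
MONOALLELIC_LIKE = frozenset(
    {
        AllelicRequirement.MONOALLELIC,
        AllelicRequirement.HEMIZYGOUS,
        AllelicRequirement.X_LINKED_DOMINANT,
        AllelicRequirement.X_LINKED_OVER_DOMINANCE,
        AllelicRequirement.IMPRINTED,
        AllelicRequirement.MOSAIC,
    }
)

#: Requirements the genotype-aggregation engine cannot evaluate from a
#: single proband VCF; findings are emitted as not-satisfied with a reason.
UNSUPPORTED_REQUIREMENTS = frozenset(
    {
        AllelicRequirement.DIGENIC,
        AllelicRequirement.MITOCHONDRIAL,
        AllelicRequirement.UNCERTAIN,
    }
)


class MutationConsequence(_VocabEnum):
    LOSS_OF_FUNCTION = "loss_of_function"
    ACTIVATING = "activating"
    DOMINANT_NEGATIVE = "dominant_negative"
    UTR_MUTATION = "utr_mutation"
    CIS_REGULATORY = "cis_regulatory"
    INCREASED_GENE_DOSAGE = "increased_gene_dosage"
    ALL_MISSENSE_IN_FRAME = "all_missense_in_frame"
    UNCERTAIN = "uncertain"

    @classmethod
    def _aliases(cls):
        return {
            "lof": "loss_of_function",
            "5_or_3_utr_mutation": "utr_mutation",
            "5'_or_3'utr_mutation": "utr_mutation",
            "5’_or_3’utr_mutation": "utr_mutation",
            "cis_regulatory_or_promotor_mutation": "cis_regulatory",
            "cis_regulatory_or_promoter_mutation": "cis_regulatory",
            "all_missense_in_frame_variants": "all_missense_in_frame",
            "all_missense_inframe": "all_missense_in_frame",
            "unknown": "uncertain",
        }


class ConsequenceClass(_VocabEnum):
    """Coarse variant-consequence classes used for filtering and stratification."""

    LOF = "lof"
    MISSENSE = "missense"
    INFRAME = "inframe"
    SPLICE_REGION = "splice_region"
    OTHER = "other"


#: Severity order used when one transcript annotation must win (lower = worse).
CLASS_SEVERITY: dict[ConsequenceClass, int] = {
    ConsequenceClass.LOF: 0,
    ConsequenceClass.MISSENSE: 1,
    ConsequenceClass.INFRAME: 2,
    ConsequenceClass.SPLICE_REGION: 3,
    ConsequenceClass.OTHER: 4,
}


class Zygosity(_VocabEnum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI = "hemi"
    NO_CALL = "no_call"

    @property
    def carries_alt(self) -> bool:
        return self in (Zygosity.HET, Zygosity.HOM_ALT, Zygosity.HEMI)


class Sex(_VocabEnum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def _aliases(cls):
        return {"1": "male", "2": "female", "0": "unknown", "m": "male", "f": "female"}
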