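"""Gene-panel datasets: reading, validation, querying and summaries.

A panel is a list of curated gene-to-disease associations.  Each entry
(one *locus-genotype-mechanism-disease-evidence thread*, LGMDET) links a
gene, via an allelic requirement and a mutation consequence, to a disease,
together with a curation confidence, phenotype terms and literature
evidence.  A gene may carry several entries (e.g. monoallelic/activating
and biallelic/loss-of-function threads for the same locus), and the panel
index returns all of them.

Two on-disk formats are supported: the panel CSV download format (one
entry per row, semicolon-delimited multi-valued cells) and tab-separated
PanelApp-style exports, which are converted into the same internal model.
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import FormatError, ValidationError
from .vocab import AllelicRequirement, Confidence, MutationConsequence

logger = logging.getLogger(__name__)

__all__ = [
    "LGMDET",
    "Panel",
    "read_g2p_csv",
    "write_g2p_csv",
    "reportable_entries",
    "read_panelapp",
    "panel_summary",
]

#: Default mapping from logical column names to CSV header names.  The
#: public download format is not byte-specified, so callers may override
#: any of these (e.g. ``{"gene_symbol": "gene symbol"}``).
DEFAULT_COLUMNS: dict[str, str] = {
    "gene_symbol": "gene symbol",
    "gene_ids": "gene mim",
    "disease_name": "disease name",
    "confidence": "confidence category",
    "allelic_requirement": "allelic requirement",
    "mutation_consequence": "mutation consequence",
    "hpo_terms": "phenotypes",
    "organ_specificity": "organ specificity list",
    "pmids": "pmids",
}

_REQUIRED = (
    "gene_symbol",
    "disease_name",
    "confidence",
    "allelic_requirement",
    "mutation_consequence",
)

_MULTI_SEP = ";"


@dataclass(frozen=True)
class LGMDET:
    """One curated gene-disease thread with its genotype/mechanism contract."""

    gene_symbol: str
    disease_name: str
    confidence: Confidence
    allelic_requirement: AllelicRequirement
    mutation_consequence: MutationConsequence
    gene_ids: tuple[str, ...] = ()
    hpo_terms: tuple[str, ...] = ()
    organ_specificity: tuple[str, ...] = ()
    pmids: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.gene_symbol or not self.gene_symbol.strip():
            raise ValidationError("LGMDET gene_symbol must be non-empty")
        object.__setattr__(self, "gene_symbol", self.gene_symbol.strip())

    @property
    def reportable(self) -> bool:
        return self.confidence.reportable

    @property
    def incidental_flag(self) -> bool:
        """True for entries relevant both to the referred disease and incidentally."""
        return self.confidence is Confidence.BOTH_RD_AND_IF


@dataclass
class Panel:
    """An ordered collection of LGMDETs with a gene-symbol index."""

    name: str = "panel"
    entries: list[LGMDET] = field(default_factory=list)

    def __post_init__(self):
        self._index: dict[str, list[LGMDET]] = {}
        for e in self.entries:
            self._index.setdefault(e.gene_symbol, []).append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def genes(self) -> list[str]:
        return list(self._index)

    def entries_for_gene(self, gene_symbol: str) -> list[LGMDET]:
        """All threads curated for a gene (a gene may carry several)."""
        return list(self._index.get(gene_symbol, ()))

    def __contains__(self, gene_symbol: str) -> bool:
        return gene_symbol in self._index


def _split_multi(cell: str | None) -> tuple[str, ...]:
    if cell is None:
        return ()
    return tuple(p.strip() for p in str(cell).split(_MULTI_SEP) if p.strip())


def _row_to_entry(row: Mapping[str, str], columns: Mapping[str, str], row_no: int) -> LGMDET:
    def get(logical: str) -> str | None:
        col = columns.get(logical)
        if col is None or col not in row:
            return None
        return row[col]

    try:
        return LGMDET(
            gene_symbol=str(get("gene_symbol") or ""),
            disease_name=str(get("disease_name") or "").strip(),
            confidence=Confidence.parse(get("confidence")),
            allelic_requirement=AllelicRequirement.parse(get("allelic_requirement")),
            mutation_consequence=MutationConsequence.parse(get("mutation_consequence")),
            gene_ids=_split_multi(get("gene_ids")),
            hpo_terms=_split_multi(get("hpo_terms")),
            organ_specificity=_split_multi(get("organ_specificity")),
            pmids=_split_multi(get("pmids")),
        )
    except ValidationError as exc:
        raise ValidationError(f"row {row_no}: {exc}") from None


def read_g2p_csv(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    delimiter: str = ",",
    name: str | None = None,
) -> Panel:
    """Read a panel CSV into a :class:`Panel`, preserving row order.

    Parameters
    ----------
    path
        CSV file with one header row and one entry per data row.
    columns
        Overrides for :data:`DEFAULT_COLUMNS` (logical name -> header name).
    delimiter
        Field delimiter; the download format is comma-separated.

    Raises
    ------
    FormatError
        If a required column is missing from the header.
    ValidationError
        If a vocabulary cell holds an unknown value (the message names the
        offending row and value).
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for logical in _REQUIRED:
            if cols[logical] not in header:
                raise FormatError(
                    f"{path}: required column {cols[logical]!r} ({logical}) "
                    f"missing from header {header}"
                )
        entries = [_row_to_entry(row, cols, i) for i, row in enumerate(reader, start=2)]
    return Panel(name=name or path.stem, entries=entries)


def write_g2p_csv(panel: Panel, path: str | Path, columns: Mapping[str, str] | None = None) -> None:
    """Write a panel back to the CSV format read by :func:`read_g2p_csv`."""
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    order = list(cols)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([cols[k] for k in order])
        for e in panel:
            row = {
                "gene_symbol": e.gene_symbol,
                "gene_ids": _MULTI_SEP.join(e.gene_ids),
                "disease_name": e.disease_name,
                "confidence": e.confidence.value,
                "allelic_requirement": e.allelic_requirement.value,
                "mutation_consequence": e.mutation_consequence.value,
                "hpo_terms": _MULTI_SEP.join(e.hpo_terms),
                "organ_specificity": _MULTI_SEP.join(e.organ_specificity),
                "pmids": _MULTI_SEP.join(e.pmids),
            }
            writer.writerow([row[k] for k in order])


def reportable_entries(panel: Panel) -> Panel:
    """Restrict a panel to clinically reportable entries.

    Confirmed, probable and RD+IF threads are reportable; possible threads
    are excluded.  The input panel is not modified; the operation is
    idempotent.
    """
    return Panel(name=panel.name, entries=[e for e in panel if e.reportable])


#: Default PanelApp rating -> confidence mapping (traffic-light ratings).
PANELAPP_CONFIDENCE: dict[str, Confidence] = {
    "green": Confidence.CONFIRMED,
    "amber": Confidence.PROBABLE,
    "red": Confidence.POSSIBLE,
    "3": Confidence.CONFIRMED,
    "2": Confidence.PROBABLE,
    "1": Confidence.POSSIBLE,
}

#: Mode-of-inheritance phrases seen in PanelApp exports -> allelic requirement.
PANELAPP_MOI: dict[str, AllelicRequirement] = {
    "monoallelic": AllelicRequirement.MONOALLELIC,
    "biallelic": AllelicRequirement.BIALLELIC,
    "monoallelic_autosomal_dominant": AllelicRequirement.MONOALLELIC,
    "biallelic_autosomal_recessive": AllelicRequirement.BIALLELIC,
    "x_linked": AllelicRequirement.HEMIZYGOUS,
    "x_linked_recessive": AllelicRequirement.HEMIZYGOUS,
    "hemizygous": AllelicRequirement.HEMIZYGOUS,
    "x_linked_dominant": AllelicRequirement.X_LINKED_DOMINANT,
    "imprinted": AllelicRequirement.IMPRINTED,
    "mosaic": AllelicRequirement.MOSAIC,
    "mitochondrial": AllelicRequirement.MITOCHONDRIAL,
    "digenic": AllelicRequirement.DIGENIC,
}


def _map_moi(moi: str | None) -> AllelicRequirement:
    from .vocab import _normalise  # shared normaliser

    if not moi:
        return AllelicRequirement.UNCERTAIN
    key = _normalise(moi)
    if key in PANELAPP_MOI:
        return PANELAPP_MOI[key]
    # Phrase-level fallback: exports embed MOI in longer sentences.
    for fragment, req in PANELAPP_MOI.items():
        if fragment in key:
            return req
    logger.warning("unmappable mode of inheritance %r; using 'uncertain'", moi)
    return AllelicRequirement.UNCERTAIN


def read_panelapp(
    path: str | Path,
    confidence_map: Mapping[str, Confidence] | None = None,
    gene_column: str = "Entity Name",
    rating_column: str = "Rating",
    moi_column: str = "Mode of inheritance",
    disease_column: str | None = "Phenotypes",
    name: str | None = None,
) -> Panel:
    """Convert a tab-separated PanelApp-style export into a :class:`Panel`.

    Ratings map to confidence via ``confidence_map`` (default: green →
    confirmed, amber → probable, red → possible).  Mode-of-inheritance
    strings map to allelic requirements; unmappable strings become
    ``uncertain`` with a logged warning.  PanelApp carries no mutation
    consequence, so it defaults to ``uncertain``.
    """
    path = Path(path)
    cmap = {k.lower(): v for k, v in (confidence_map or PANELAPP_CONFIDENCE).items()}
    entries: list[LGMDET] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        if gene_column not in header:
            raise FormatError(f"{path}: gene column {gene_column!r} missing from header {header}")
        for i, row in enumerate(reader, start=2):
            rating = (row.get(rating_column) or "").strip().lower()
            confidence = cmap.get(rating)
            if confidence is None:
                logger.warning("row %d: unmappable rating %r; using 'possible'", i, rating)
                confidence = Confidence.POSSIBLE
            entries.append(
                LGMDET(
                    gene_symbol=row[gene_column],
                    disease_name=(row.get(disease_column) or "").split(_MULTI_SEP)[0].strip()
                    if disease_column
                    else "",
                    confidence=confidence,
                    allelic_requirement=_map_moi(row.get(moi_column)),
                    mutation_consequence=MutationConsequence.UNCERTAIN,
                )
            )
    return Panel(name=name or path.stem, entries=entries)


def panel_summary(panel: Panel) -> dict[str, pd.DataFrame]:
    """Tabulate entries by confidence, allelic requirement and mutation consequence.

    Percentages are computed over *reportable* entries only, mirroring how
    panel freezes are reported: the possible category is listed with a
    count but no percentage, and every other facet row is a percentage of
    the reportable total.

    Returns a mapping of facet name to a DataFrame with ``count`` and
    ``percent`` columns (percent is NaN for non-reportable rows).
    """
    reportable = [e for e in panel if e.reportable]
    n_rep = len(reportable)

    def facet(attr: str, universe, include_all: bool) -> pd.DataFrame:
        source = panel.entries if include_all else reportable
        counts = Counter(getattr(e, attr) for e in source)
        rows = []
        for member in universe:
            c = counts.get(member, 0)
            pct = round(100.0 * c / n_rep, 1) if (n_rep and member.value != "possible") else float("nan")
            rows.append({"category": member.value, "count": c, "percent": pct})
        return pd.DataFrame(rows).set_index("category")

    out = {
        "confidence": facet("confidence", Confidence, include_all=True),
        "allelic_requirement": facet("allelic_requirement", AllelicRequirement, include_all=False),
        "mutation_consequence": facet("mutation_consequence", MutationConsequence, include_all=False),
    }
    out["totals"] = pd.DataFrame(
        [
            {"category": "reportable_entries", "count": n_rep, "percent": 100.0 if n_rep else float("nan")},
            {
                "category": "reportable_genes",
                "count": len({e.gene_symbol for e in reportable}),
                "percent": float("nan"),
            },
        ]
    ).set_index("category")
    return out
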