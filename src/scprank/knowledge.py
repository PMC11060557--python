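"""Prior-knowledge checklists and drug mode-of-action (MOA) expansion.

A checklist is the structured form of expert/database prior knowledge about a
disease: ordered lists of pathway terms (one list per gene-set collection),
an ordered drug list, and optionally an ordered list of MOA keywords.  Order
encodes relevance — index 1 is the term the user (or the source database's
enrichment score) considers most strongly disease-associated — and is
preserved exactly through every operation.

Two modes are supported:

* ``discovery`` — the checklist is taken wholesale from a disease-database
  export (pathways, drugs, optionally MOAs).
* ``hypothesis`` — the user supplies keywords; drug names are typically not
  known up front, so MOA keywords are expanded into concrete drugs through a
  drug-repurposing-hub style lookup table (:func:`expand_moas`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "Checklist",
    "MOATable",
    "load_checklist",
    "save_checklist",
    "load_moa_table",
    "expand_moas",
    "normalize_term",
]

MODES = ("discovery", "hypothesis")

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Case-fold, trim, and collapse internal whitespace.

    Disease databases and enrichment backends capitalize the same pathway
    differently; all term comparison in the pipeline goes through this
    normal form.
    """
    return _WS.sub(" ", term.strip()).casefold()


def _check_ordered_unique(terms: Sequence[str], where: str) -> None:
    seen: dict[str, str] = {}
    for t in terms:
        if not str(t).strip():
            raise ValueError(f"{where}: empty term entry")
        key = normalize_term(str(t))
        if key in seen:
            raise ValueError(
                f"{where}: duplicate term after normalization: {key!r} "
                f"(entries {seen[key]!r} and {t!r})"
            )
        seen[key] = str(t)


@dataclass(frozen=True)
class Checklist:
    """Ordered prior-knowledge terms for one disease.

    Attributes
    ----------
    disease_name:
        Free-text disease label; carried into reports.
    mode:
        ``"discovery"`` or ``"hypothesis"``.
    pathway_terms:
        Mapping collection-name -> ordered list of pathway terms.  Each
        collection name must correspond to a loaded gene-set collection at
        pipeline assembly time.
    drug_terms:
        Ordered drug names (may be empty in hypothesis mode before MOA
        expansion).
    moa_terms:
        Ordered MOA keywords (may be empty).
    """

    disease_name: str
    mode: str
    pathway_terms: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    drug_terms: tuple[str, ...] = ()
    moa_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        object.__setattr__(
            self,
            "pathway_terms",
            {str(c): tuple(str(t) for t in ts) for c, ts in self.pathway_terms.items()},
        )
        object.__setattr__(self, "drug_terms", tuple(str(t) for t in self.drug_terms))
        object.__setattr__(self, "moa_terms", tuple(str(t) for t in self.moa_terms))
        for coll, terms in self.pathway_terms.items():
            _check_ordered_unique(terms, f"pathways.{coll}")
        _check_ordered_unique(self.drug_terms, "drugs")
        _check_ordered_unique(self.moa_terms, "moas")

    @property
    def collections(self) -> tuple[str, ...]:
        return tuple(self.pathway_terms)


@dataclass(frozen=True)
class MOATable:
    """Many-to-many drug <-> mechanism-of-action lookup.

    Rows are ``(drug_name, moa)`` pairs; one drug may carry several MOA
    annotations and one MOA maps to many drugs.  Lookups are
    case-insensitive substring matches on the MOA column, because MOA
    annotations in repurposing-hub exports are multi-valued free text
    (e.g. ``"MTOR inhibitor|autophagy inducer"``).
    """

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        cleaned = []
        for drug, moa in self.rows:
            drug, moa = str(drug).strip(), str(moa).strip()
            if not drug or not moa:
                raise ValueError("MOA table rows must have non-empty drug and moa fields")
            cleaned.append((drug, moa))
        object.__setattr__(self, "rows", tuple(cleaned))

    def drugs_for(self, keyword: str) -> list[str]:
        """All drugs whose MOA annotation contains *keyword*, in table order.

        Duplicate drugs keep their first occurrence.
        """
        key = normalize_term(keyword)
        out: list[str] = []
        seen: set[str] = set()
        for drug, moa in self.rows:
            if key in normalize_term(moa):
                dkey = normalize_term(drug)
                if dkey not in seen:
                    seen.add(dkey)
                    out.append(drug)
        return out


def load_checklist(path: str | Path, mode: str | None = None) -> Checklist:
    """Read a checklist from a YAML file.

    Expected layout (every list ordered, most relevant first)::

        disease: COVID-19
        mode: discovery          # optional here, may be given as argument
        pathways:
          KEGG: [Coronavirus disease, NF-kappa B signaling]
          WIKI: [...]
        drugs: [dexamethasone, baricitinib]
        moas: [JAK inhibitor]

    ``mode`` passed as an argument overrides the file's ``mode`` key.
    Duplicate terms (after normalization) raise with the offending term.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checklist file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"checklist file {path} is not a mapping")
    eff_mode = mode or raw.get("mode")
    if eff_mode is None:
        raise ValueError("checklist mode not given in file or argument")
    pathways = raw.get("pathways") or {}
    if not isinstance(pathways, dict):
        raise ValueError("'pathways' must map collection names to term lists")
    return Checklist(
        disease_name=str(raw.get("disease", path.stem)),
        mode=str(eff_mode),
        pathway_terms={str(c): tuple(ts or ()) for c, ts in pathways.items()},
        drug_terms=tuple(raw.get("drugs") or ()),
        moa_terms=tuple(raw.get("moas") or ()),
    )


def save_checklist(checklist: Checklist, path: str | Path) -> None:
    """Write a checklist back to YAML; round-trips through :func:`load_checklist`."""
    doc = {
        "disease": checklist.disease_name,
        "mode": checklist.mode,
        "pathways": {c: list(ts) for c, ts in checklist.pathway_terms.items()},
        "drugs": list(checklist.drug_terms),
        "moas": list(checklist.moa_terms),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def load_moa_table(path: str | Path) -> MOATable:
    """Read a two-column TSV ``drug_name<TAB>moa`` (with header) into a MOATable."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"MOA table not found: {path}")
    rows: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip().casefold() for h in header[:2]] != ["drug_name", "moa"]:
            raise ValueError(
                f"MOA table must start with header 'drug_name<TAB>moa', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            rows.append((parts[0], parts[1]))
    return MOATable(tuple(rows))


def expand_moas(checklist: Checklist, moas: MOATable) -> Checklist:
    """Expand MOA keywords into concrete drug names.

    For each MOA keyword, in checklist order, all drugs whose MOA annotation
    contains the keyword (case-insensitive) are appended; duplicates keep the
    first occurrence.  The resulting drug list *replaces* ``drug_terms``;
    ``moa_terms`` are retained, so the operation is idempotent.

    Raises
    ------
    ValueError
        If the checklist is not in hypothesis mode, has no MOA keywords, or
        no keyword matches any table row.
    """
    if checklist.mode != "hypothesis":
        raise ValueError("MOA expansion applies to hypothesis-mode checklists only")
    if not checklist.moa_terms:
        raise ValueError("checklist has no MOA keywords to expand")
    drugs: list[str] = []
    seen: set[str] = set()
    for kw in checklist.moa_terms:
        for drug in moas.drugs_for(kw):
            key = normalize_term(drug)
            if key not in seen:
                seen.add(key)
                drugs.append(drug)
    if not drugs:
        raise ValueError(
            "no drug in the MOA table matches any checklist MOA keyword; "
            "revise the keywords (e.g. use the table's MOA vocabulary)"
        )
    return replace(checklist, drug_terms=tuple(drugs))
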