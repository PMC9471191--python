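"""Drug-tier knowledge for guideline-concordance scoring.

The stepwise CANMAT 2016 recommendations are shipped as two editable
tab-separated data files rather than hard-coded:

* ``data/drug_catalog.tsv`` — the drug vocabulary (generic name, class,
  antidepressant flag);
* ``data/canmat_tiers.tsv`` — the drug → line-of-treatment mapping for
  monotherapy and adjunctive roles plus the superior-efficacy flag.

All concordance logic performs lookups against a loaded
:class:`CanmatTierTable`; no drug name appears in decision code.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

AD_CLASSES = frozenset(
    {
        "SSRI",
        "SNRI",
        "TCA",
        "NaSSA",
        "other_AD",
        "antipsychotic",
        "mood_stabilizer",
        "other_adjunct",
    }
)

LINES = ("first", "second", "third")
_LINE_FROM_INT = {1: "first", 2: "second", 3: "third"}
_INT_FROM_LINE = {v: k for k, v in _LINE_FROM_INT.items()}

UNLISTED = "unlisted"


class TierTableError(ValueError):
    """Malformed or internally inconsistent tier-table / catalog input."""


@dataclass(frozen=True)
class DrugEntry:
    """One catalog row: canonical lowercase generic name plus class flags."""

    drug_id: str
    ad_class: str
    is_antidepressant: bool

    def __post_init__(self) -> None:
        if self.ad_class not in AD_CLASSES:
            raise TierTableError(
                f"unknown ad_class {self.ad_class!r} for drug {self.drug_id!r}"
            )


@dataclass(frozen=True)
class DrugCatalog:
    """Immutable drug vocabulary keyed by ``drug_id``."""

    entries: Mapping[str, DrugEntry]

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.entries

    def __getitem__(self, drug_id: str) -> DrugEntry:
        try:
            return self.entries[drug_id]
        except KeyError:
            raise TierTableError(f"drug {drug_id!r} not in catalog") from None

    def is_antidepressant(self, drug_id: str) -> bool:
        return self[drug_id].is_antidepressant

    @property
    def antidepressants(self) -> frozenset[str]:
        return frozenset(
            d for d, e in self.entries.items() if e.is_antidepressant
        )


@dataclass(frozen=True)
class CanmatTierTable:
    """Drug → line-of-treatment mapping for monotherapy and adjunct roles.

    ``switch_eligible_lines`` / ``adjunct_eligible_lines`` make the
    concordance rule configurable: by default a switch is concordant when
    the target drug carries the superior-efficacy flag or is a second- or
    third-line monotherapy agent, while any listed adjunct line counts for
    an add-on.
    """

    monotherapy_line: Mapping[str, str]
    superior_efficacy: frozenset[str]
    adjunct_line: Mapping[str, str]
    switch_eligible_lines: frozenset[str] = frozenset({"second", "third"})
    adjunct_eligible_lines: frozenset[str] = frozenset(LINES)
    switch_allow_any_first_line: bool = False

    def __post_init__(self) -> None:
        bad = self.superior_efficacy - set(self.monotherapy_line)
        if bad:
            raise TierTableError(
                f"superior_efficacy drugs missing from monotherapy lines: {sorted(bad)}"
            )
        for m in (self.monotherapy_line, self.adjunct_line):
            for drug, line in m.items():
                if line not in LINES:
                    raise TierTableError(f"bad line {line!r} for drug {drug!r}")

    def with_config(
        self,
        *,
        switch_allow_any_first_line: bool | None = None,
        adjunct_eligible_lines: Iterable[str] | None = None,
    ) -> "CanmatTierTable":
        """Return a copy with altered concordance-rule configuration."""
        kwargs = {}
        if switch_allow_any_first_line is not None:
            kwargs["switch_allow_any_first_line"] = switch_allow_any_first_line
        if adjunct_eligible_lines is not None:
            kwargs["adjunct_eligible_lines"] = frozenset(adjunct_eligible_lines)
        return replace(self, **kwargs)

    # -- lookups -----------------------------------------------------------

    def monotherapy_status(self, drug_id: str) -> str:
        return self.monotherapy_line.get(drug_id, UNLISTED)

    def adjunct_status(self, drug_id: str) -> str:
        return self.adjunct_line.get(drug_id, UNLISTED)

    def switch_concordant(self, drug_id: str) -> bool:
        """Is a single-drug switch to ``drug_id`` algorithm-concordant?"""
        if drug_id in self.superior_efficacy:
            return True
        line = self.monotherapy_status(drug_id)
        if line in self.switch_eligible_lines:
            return True
        return self.switch_allow_any_first_line and line == "first"

    def adjunct_concordant(self, drug_id: str) -> bool:
        """Is a single-drug add-on of ``drug_id`` algorithm-concordant?"""
        return self.adjunct_status(drug_id) in self.adjunct_eligible_lines


def default_catalog_path() -> Path:
    return Path(str(resources.files("adpatterns") / "data" / "drug_catalog.tsv"))


def default_tier_table_path() -> Path:
    return Path(str(resources.files("adpatterns") / "data" / "canmat_tiers.tsv"))


def load_catalog(path: str | Path | None = None) -> DrugCatalog:
    """Read a drug catalog (TSV: drug_id, ad_class, is_antidepressant)."""
    path = default_catalog_path() if path is None else Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TierTableError(f"cannot parse catalog {path}: {exc}") from exc
    required = {"drug_id", "ad_class", "is_antidepressant"}
    if df.empty or not required.issubset(df.columns):
        raise TierTableError(
            f"catalog {path} must have columns {sorted(required)} and at least one row"
        )
    entries: dict[str, DrugEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        drug = str(row.drug_id).strip().lower()
        if drug in entries:
            raise TierTableError(f"{path}:{i}: duplicate drug_id {drug!r}")
        entries[drug] = DrugEntry(
            drug_id=drug,
            ad_class=str(row.ad_class).strip(),
            is_antidepressant=str(row.is_antidepressant).strip() in {"1", "true", "True"},
        )
    return DrugCatalog(entries=entries)


def load_tier_table(
    path: str | Path | None = None,
    catalog: DrugCatalog | None = None,
    **config,
) -> CanmatTierTable:
    """Read a tier table (TSV: drug_id, role, line, superior_efficacy).

    Every drug must resolve in ``catalog``; unknown drugs are reported by
    name.  Extra keyword arguments are forwarded to
    :meth:`CanmatTierTable.with_config`.
    """
    path = default_tier_table_path() if path is None else Path(path)
    catalog = load_catalog() if catalog is None else catalog
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise TierTableError(f"cannot parse tier table {path}: {exc}") from exc
    required = {"drug_id", "role", "line", "superior_efficacy"}
    if df.empty or not required.issubset(df.columns):
        raise TierTableError(
            f"tier table {path} must have columns {sorted(required)} and at least one row"
        )
    mono: dict[str, str] = {}
    adjunct: dict[str, str] = {}
    superior: set[str] = set()
    unknown: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        drug = str(row.drug_id).strip().lower()
        if drug not in catalog:
            unknown.append(drug)
            continue
        role = str(row.role).strip()
        try:
            line = _LINE_FROM_INT[int(row.line)]
        except (KeyError, ValueError):
            raise TierTableError(f"{path}:{i}: line must be 1, 2 or 3") from None
        if role == "monotherapy":
            if drug in mono:
                raise TierTableError(f"{path}:{i}: duplicate monotherapy row for {drug!r}")
            mono[drug] = line
            if str(row.superior_efficacy).strip() == "1":
                superior.add(drug)
        elif role == "adjunct":
            if drug in adjunct:
                raise TierTableError(f"{path}:{i}: duplicate adjunct row for {drug!r}")
            adjunct[drug] = line
        else:
            raise TierTableError(f"{path}:{i}: role must be monotherapy or adjunct")
    if unknown:
        raise TierTableError(f"tier table drugs not in catalog: {sorted(set(unknown))}")
    table = CanmatTierTable(
        monotherapy_line=mono,
        superior_efficacy=frozenset(superior),
        adjunct_line=adjunct,
    )
    return table.with_config(**config) if config else table


def write_tier_table(table: CanmatTierTable, path: str | Path) -> None:
    """Serialize a tier table in the same TSV layout ``load_tier_table`` reads."""
    rows = [
        {
            "drug_id": d,
            "role": "monotherapy",
            "line": _INT_FROM_LINE[line],
            "superior_efficacy": int(d in table.superior_efficacy),
        }
        for d, line in table.monotherapy_line.items()
    ]
    rows += [
        {"drug_id": d, "role": "adjunct", "line": _INT_FROM_LINE[line], "superior_efficacy": 0}
        for d, line in table.adjunct_line.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def monotherapy_status(table: CanmatTierTable, drug_id: str, catalog: DrugCatalog | None = None) -> str:
    """Line of ``drug_id`` as monotherapy: first/second/third or unlisted."""
    if catalog is not None and drug_id not in catalog:
        raise TierTableError(f"drug {drug_id!r} not in catalog")
    return table.monotherapy_status(drug_id)


def adjunct_status(table: CanmatTierTable, drug_id: str, catalog: DrugCatalog | None = None) -> str:
    """Line of ``drug_id`` as adjunctive agent: first/second/third or unlisted."""
    if catalog is not None and drug_id not in catalog:
        raise TierTableError(f"drug {drug_id!r} not in catalog")
    return table.adjunct_status(drug_id)
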