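"""Gene-panel data model and clinical-suspicion → gene mapping.

A *panel* is a curated set of kidney-disease genes, each tagged with its
mode(s) of inheritance, the clinical-suspicion categories it can explain,
optional digenic partner genes, and whether loss of function is an
established disease mechanism.  Panels are versioned so that negative
cases can be re-analysed when the gene list is updated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping


class PanelError(ValueError):
    """Raised when a panel file violates the panel invariants."""


class InheritanceMode(str, Enum):
    """Mode of inheritance of a gene-disease association.

    ``AD_AR`` marks genes with both dominant and recessive disease forms
    (e.g. the collagen-IV glomerulopathies); it expands to ``{AD, AR}``
    whenever compatibility is queried.
    """

    AD = "AD"
    AR = "AR"
    XL = "XL"
    AD_AR = "AD_AR"

    def expand(self) -> frozenset["InheritanceMode"]:
        if self is InheritanceMode.AD_AR:
            return frozenset({InheritanceMode.AD, InheritanceMode.AR})
        return frozenset({self})


class SuspicionCategory(str, Enum):
    """Closed set of clinical-suspicion categories used at recruitment."""

    CAKUT = "CAKUT"
    TUBULAR = "TUBULAR"
    CILIOPATHY = "CILIOPATHY"
    NEPHROLITHIASIS_NEPHROCALCINOSIS = "NEPHROLITHIASIS_NEPHROCALCINOSIS"
    GLOMERULAR = "GLOMERULAR"
    HUS = "HUS"
    UNKNOWN_ORIGIN = "UNKNOWN_ORIGIN"
    OTHER = "OTHER"


#: Categories with no tailored gene list: they fall through to the whole panel.
BROAD_CATEGORIES = frozenset(
    {SuspicionCategory.UNKNOWN_ORIGIN, SuspicionCategory.OTHER}
)

VALID_CHROMOSOMES = frozenset(
    {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}
)


def normalize_chromosome(chrom: str) -> str:
    """Strip a ``chr`` prefix and canonicalise mitochondrial names."""
    c = chrom.removeprefix("chr")
    if c in {"M", "Mt"}:
        c = "MT"
    return c


def expand_modes(modes: Iterable[InheritanceMode]) -> frozenset[InheritanceMode]:
    out: set[InheritanceMode] = set()
    for m in modes:
        out |= m.expand()
    return frozenset(out)


@dataclass(frozen=True)
class GeneEntry:
    """One panel gene with its inheritance and phenotype metadata."""

    symbol: str
    chromosome: str
    modes: frozenset[InheritanceMode]
    categories: frozenset[SuspicionCategory]
    digenic_partners: frozenset[str] = frozenset()
    lof_mechanism: bool = True

    def __post_init__(self) -> None:
        if not self.symbol:
            raise PanelError("gene symbol must be non-empty")
        if not self.modes:
            raise PanelError(f"{self.symbol}: at least one inheritance mode required")
        if not self.categories:
            raise PanelError(f"{self.symbol}: at least one suspicion category required")
        if self.chromosome not in VALID_CHROMOSOMES:
            raise PanelError(
                f"{self.symbol}: invalid chromosome {self.chromosome!r}"
            )

    @property
    def compatible_modes(self) -> frozenset[InheritanceMode]:
        """Modes after AD_AR expansion (subset of {AD, AR, XL})."""
        return expand_modes(self.modes)

    @property
    def on_x(self) -> bool:
        return self.chromosome == "X"

    @property
    def ar_only(self) -> bool:
        return self.compatible_modes == frozenset({InheritanceMode.AR})


@dataclass
class Panel:
    """A versioned mapping of gene symbols to :class:`GeneEntry`."""

    entries: dict[str, GeneEntry]
    version: str
    updated: date | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.entries:
            raise PanelError("panel must contain at least one gene")
        for symbol, entry in self.entries.items():
            if symbol != entry.symbol:
                raise PanelError(
                    f"entry keyed {symbol!r} carries symbol {entry.symbol!r}"
                )
            for partner in entry.digenic_partners:
                if partner not in self.entries:
                    raise PanelError(
                        f"{symbol}: digenic partner {partner!r} not in panel"
                    )

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.entries)

    def genes_for_suspicion(
        self, suspicion: SuspicionCategory
    ) -> frozenset[GeneEntry]:
        return genes_for_suspicion(self, suspicion)


def genes_for_suspicion(
    panel: Panel, suspicion: SuspicionCategory
) -> frozenset[GeneEntry]:
    """Tailored gene list for a clinical suspicion.

    Unknown-origin and "other" presentations have no tailored list and map
    to the full panel; a category no panel gene is tagged with yields the
    empty set (the caller then falls through to the full-panel pass).
    """
    suspicion = SuspicionCategory(suspicion)
    if suspicion in BROAD_CATEGORIES:
        return frozenset(panel.entries.values())
    return frozenset(
        e for e in panel.entries.values() if suspicion in e.categories
    )


@dataclass(frozen=True)
class PanelDiff:
    added: frozenset[str]
    removed: frozenset[str]
    changed: frozenset[str]

    @property
    def empty(self) -> bool:
        return not (self.added or self.removed or self.changed)


def panel_diff(old: Panel, new: Panel) -> PanelDiff:
    """Symbols added, removed, or whose entry metadata changed."""
    old_syms, new_syms = old.symbols, new.symbols
    common = old_syms & new_syms
    return PanelDiff(
        added=frozenset(new_syms - old_syms),
        removed=frozenset(old_syms - new_syms),
        changed=frozenset(
            s for s in common if old.entries[s] != new.entries[s]
        ),
    )


# ---------------------------------------------------------------------------
# File formats: TSV (with a `version:` pragma) and JSON.
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "symbol",
    "chromosome",
    "modes",
    "categories",
    "digenic_partners",
    "lof_mechanism",
]


def _parse_set(raw: str) -> list[str]:
    raw = raw.strip()
    if not raw or raw == ".":
        return []
    return [tok.strip() for tok in raw.split(",") if tok.strip()]


def _entry_from_fields(fields: Mapping[str, str], where: str) -> GeneEntry:
    try:
        modes = frozenset(InheritanceMode(m) for m in _parse_set(fields["modes"]))
    except ValueError as exc:
        raise PanelError(f"{where}: unknown inheritance mode ({exc})") from exc
    try:
        categories = frozenset(
            SuspicionCategory(c) for c in _parse_set(fields["categories"])
        )
    except ValueError as exc:
        raise PanelError(f"{where}: unknown suspicion category ({exc})") from exc
    lof_raw = str(fields.get("lof_mechanism", "true")).strip().lower()
    if lof_raw not in {"true", "false", "1", "0"}:
        raise PanelError(f"{where}: lof_mechanism must be boolean, got {lof_raw!r}")
    return GeneEntry(
        symbol=fields["symbol"].strip(),
        chromosome=normalize_chromosome(fields["chromosome"].strip()),
        modes=modes,
        categories=categories,
        digenic_partners=frozenset(_parse_set(fields.get("digenic_partners", ""))),
        lof_mechanism=lof_raw in {"true", "1"},
    )


def _load_panel_tsv(path: Path) -> Panel:
    version: str | None = None
    header: list[str] | None = None
    entries: dict[str, GeneEntry] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("version:"):
            version = line.split(":", 1)[1].strip()
            continue
        if line.startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            missing = [c for c in _TSV_COLUMNS[:4] if c not in header]
            if missing:
                raise PanelError(f"{path}:{lineno}: missing columns {missing}")
            continue
        fields = dict(zip(header, cells))
        where = f"{path}:{lineno}"
        entry = _entry_from_fields(fields, where)
        if entry.symbol in entries:
            raise PanelError(f"{where}: duplicate symbol {entry.symbol!r}")
        entries[entry.symbol] = entry
    if version is None:
        raise PanelError(f"{path}: missing required 'version:' pragma line")
    if header is None:
        raise PanelError(f"{path}: no header line found")
    return Panel(entries=entries, version=version)


def _load_panel_json(path: Path) -> Panel:
    doc = json.loads(path.read_text())
    if "version" not in doc:
        raise PanelError(f"{path}: missing 'version' key")
    entries: dict[str, GeneEntry] = {}
    for i, rec in enumerate(doc.get("genes", [])):
        fields = {
            "symbol": rec["symbol"],
            "chromosome": str(rec["chromosome"]),
            "modes": ",".join(rec.get("modes", [])),
            "categories": ",".join(rec.get("categories", [])),
            "digenic_partners": ",".join(rec.get("digenic_partners", [])),
            "lof_mechanism": str(rec.get("lof_mechanism", True)),
        }
        entry = _entry_from_fields(fields, f"{path}:genes[{i}]")
        if entry.symbol in entries:
            raise PanelError(f"{path}: duplicate symbol {entry.symbol!r}")
        entries[entry.symbol] = entry
    updated = None
    if doc.get("updated"):
        updated = date.fromisoformat(doc["updated"])
    return Panel(entries=entries, version=str(doc["version"]), updated=updated)


def load_panel(path: str | Path) -> Panel:
    """Load and validate a panel from a TSV or JSON file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        return _load_panel_json(path)
    return _load_panel_tsv(path)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel as TSV; ``load_panel`` of the result round-trips."""
    path = Path(path)
    lines = [f"version: {panel.version}", "\t".join(_TSV_COLUMNS)]
    for symbol in sorted(panel.entries):
        e = panel.entries[symbol]
        lines.append(
            "\t".join(
                [
                    e.symbol,
                    e.chromosome,
                    ",".join(sorted(m.value for m in e.modes)),
                    ",".join(sorted(c.value for c in e.categories)),
                    ",".join(sorted(e.digenic_partners)) or ".",
                    "true" if e.lof_mechanism else "false",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def fixture_panel() -> Panel:
    """The illustrative kidney-disease panel shipped with the package.

    This list exists to exercise the pipeline and the synthetic cohorts;
    it is NOT a clinically curated panel.
    """
    from importlib.resources import files

    data = files("nephroprior").joinpath("data/fixture_panel.tsv")
    import tempfile

    # importlib.resources may hand back a zip member; materialise to a file.
    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        fh.write(data.read_text())
        tmp = fh.name
    try:
        return load_panel(tmp)
    finally:
        Path(tmp).unlink(missing_ok=True)
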