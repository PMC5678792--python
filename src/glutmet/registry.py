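"""Curated metabolic process gene sets and substrate->product reaction routes.

A :class:`ProcessGeneSet` is a named group of HGNC gene symbols standing
for one metabolic process (an uptake transporter family, a synthesis
route's rate-limiting enzymes, ...).  The packaged defaults cover
glutamine/glutamate influx, nucleotide salvage, glycolysis and oxidative
phosphorylation, lipid, UDP-GlcNAc, asparagine, proline, serine and
glutathione metabolism — 36 lettered process groups (A1..J2).

A :class:`ReactionSpec` wires these groups into a product pathway: the
groups defining the product's activity plus one route per reactant
metabolite (its synthesis and uptake groups pooled into one predictor).
These are the inputs of the differential-contribution regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

from .errors import FormatError, NotFoundError, ValidationError

ROLES = ("uptake", "synthesis", "rate_limiting", "exchange", "antioxidant")

#: Products with packaged reactant routes.
PRODUCTS = (
    "purine",
    "pyrimidine",
    "atp",
    "lipid",
    "nucleotide",
    "udp_glcnac",
    "asparagine",
    "proline",
    "serine",
    "gsh",
)


def normalize_symbol(symbol: str) -> str:
    """Canonicalize a gene symbol: strip, uppercase, drop internal spaces.

    Spaces inside symbols ("STAB 1") are typesetting artifacts, not
    distinct identifiers.
    """
    return "".join(symbol.split()).upper()


@dataclass(frozen=True)
class ProcessGeneSet:
    """A named gene group representing one metabolic process."""

    id: str
    name: str
    genes: frozenset[str]
    role: str = "synthesis"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"process {self.id!r}: gene set is empty")
        if self.role not in ROLES:
            raise ValidationError(f"process {self.id!r}: unknown role {self.role!r}")
        bad = [g for g in self.genes if g != normalize_symbol(g)]
        if bad:
            raise ValidationError(
                f"process {self.id!r}: non-canonical symbols {sorted(bad)}"
            )


@dataclass(frozen=True)
class ReactionSpec:
    """A product pathway and the reactant routes feeding it.

    ``reactant_routes`` maps each reactant's display name to the process
    ids whose genes jointly proxy its availability (synthesis and/or
    uptake).  Splitting one metabolite into per-source predictors (as
    for glutathione: glutamate via synthesis vs via transport) is done
    by listing two routes.
    """

    product_id: str
    product_processes: tuple[str, ...]
    reactant_routes: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        if not self.reactant_routes:
            raise ValidationError(f"product {self.product_id!r}: no reactant routes")
        names = [name for name, _ in self.reactant_routes]
        if len(names) != len(set(names)):
            raise ValidationError(
                f"product {self.product_id!r}: duplicate reactant names {names}"
            )

    @property
    def reactants(self) -> dict[str, tuple[str, ...]]:
        return dict(self.reactant_routes)

    def validate_against(self, registry: "Registry") -> None:
        referenced = set(self.product_processes)
        for _, ids in self.reactant_routes:
            referenced |= set(ids)
        missing = sorted(referenced - set(registry.ids()))
        if missing:
            raise ValidationError(
                f"product {self.product_id!r} references unknown process ids {missing}"
            )


class Registry:
    """Lookup table of :class:`ProcessGeneSet` keyed by id."""

    def __init__(self, processes: list[ProcessGeneSet]):
        seen: dict[str, ProcessGeneSet] = {}
        for p in processes:
            if p.id in seen:
                raise ValidationError(f"duplicate process id {p.id!r}")
            seen[p.id] = p
        self._processes = seen

    def __len__(self) -> int:
        return len(self._processes)

    def __iter__(self) -> Iterator[ProcessGeneSet]:
        return iter(self._processes.values())

    def __contains__(self, process_id: str) -> bool:
        return process_id in self._processes

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Registry) and self._processes == other._processes

    def ids(self) -> list[str]:
        return list(self._processes)

    def lookup(self, process_id: str) -> ProcessGeneSet:
        try:
            return self._processes[process_id]
        except KeyError:
            raise NotFoundError(
                f"process id {process_id!r} not in registry "
                f"(known: {', '.join(self._processes)})"
            ) from None

    __getitem__ = lookup

    def union_genes(self, process_ids: list[str] | tuple[str, ...]) -> frozenset[str]:
        """Pooled gene symbols of several processes (for combined scores)."""
        out: set[str] = set()
        for pid in process_ids:
            out |= self.lookup(pid).genes
        return frozenset(out)


# -- GMT I/O ------------------------------------------------------------------
# GMT is tab separated: set name, description, then one gene per field.
# The description field encodes the role as "role|free text".


def _parse_description(desc: str) -> tuple[str, str]:
    if "|" in desc:
        role, name = desc.split("|", 1)
        if role in ROLES:
            return role, name
    return "synthesis", desc


def load_registry(path: str | Path | None = None) -> Registry:
    """Load process gene sets from a GMT file, or the packaged defaults."""
    if path is None:
        ref = resources.files("glutmet.data") / "table2_processes.gmt"
        text = ref.read_text()
        source = "packaged defaults"
    else:
        text = Path(path).read_text()
        source = str(path)
    processes: list[ProcessGeneSet] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{source}: line {lineno}: GMT record needs at least 3 tab-separated "
                f"fields (name, description, gene...), got {len(fields)}"
            )
        set_id, desc, *genes = fields
        role, name = _parse_description(desc)
        symbols = frozenset(normalize_symbol(g) for g in genes if g.strip())
        processes.append(ProcessGeneSet(id=set_id, name=name, genes=symbols, role=role))
    return Registry(processes)


def write_gmt(registry: Registry, path: str | Path) -> None:
    """Write a registry to GMT; round-trips through :func:`load_registry`."""
    with open(path, "w") as fh:
        for p in registry:
            genes = "\t".join(sorted(p.genes))
            fh.write(f"{p.id}\t{p.role}|{p.name}\t{genes}\n")


# -- reaction routes ----------------------------------------------------------


def load_routes(
    path: str | Path | None = None, registry: Registry | None = None
) -> dict[str, ReactionSpec]:
    """Load product routes from YAML (packaged defaults when path is None).

    When a registry is given, every referenced process id is checked.
    """
    if path is None:
        ref = resources.files("glutmet.data") / "routes.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise FormatError("routes YAML must map product ids to route definitions")
    specs: dict[str, ReactionSpec] = {}
    for product_id, entry in raw.items():
        try:
            product = tuple(entry["product"])
            reactants = tuple(
                (str(name), tuple(ids)) for name, ids in entry["reactants"].items()
            )
        except (KeyError, TypeError) as exc:
            raise FormatError(
                f"routes YAML: product {product_id!r} needs 'product' and 'reactants'"
            ) from exc
        spec = ReactionSpec(str(product_id), product, reactants)
        if registry is not None:
            spec.validate_against(registry)
        specs[str(product_id)] = spec
    return specs


def route_table(
    product_id: str,
    registry: Registry | None = None,
    routes: dict[str, ReactionSpec] | None = None,
) -> ReactionSpec:
    """Look up the reactant routes of one product pathway."""
    if registry is None:
        registry = load_registry()
    if routes is None:
        routes = load_routes(registry=registry)
    try:
        return routes[product_id]
    except KeyError:
        raise NotFoundError(
            f"unknown product {product_id!r} (known: {', '.join(routes)})"
        ) from None
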