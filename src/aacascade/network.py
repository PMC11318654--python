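"""Reaction-network data model and on-disk catalogue format.

The network is a two-compartment (intracellular / extracellular) catalogue of
species and numbered, typed reactions.  Each reaction declares which kinds of
kinetic parameters it draws (``k_cat``, ``K_ms``, ... ) rather than numeric
values; numbers are supplied per model variant by the prior-sampling machinery.

On disk a network is a directory holding a ``manifest.yaml`` (name +
compartments), a ``species.tsv`` and a ``reactions.tsv``.  The dialect is
documented in the column constants below and round-trips losslessly through
:func:`save_network` / :func:`load_network`.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "Compartment",
    "Species",
    "ReactionSpec",
    "Network",
    "NetworkError",
    "load_network",
    "save_network",
    "validate_network",
    "species_ref",
    "parse_ref",
]

#: reaction types understood by the simulator
REACTION_TYPES = (
    "substrate_release",
    "protein_induction",
    "enzymatic",
    "non_enzymatic",
    "transport",
    "degradation",
)

#: parameter kinds a reaction may draw
PARAMETER_KINDS = (
    "k_cat",
    "K_ms",
    "K_mp",
    "K_eq",
    "k_f",
    "k_r",
    "k_deg",
    "enzyme_conc_0",
)

SPECIES_ROLES = ("metabolite", "enzyme", "transporter", "source")

#: kinds required per reaction type.  Transport reactions draw only the
#: substrate's K_m; the turnover number and starting concentration of a
#: transporter are shared across the reactions it serves and attached to the
#: transporter species itself (priors ``k_cat_<id>`` / ``enzyme_conc_0_<id>``).
REQUIRED_KINDS = {
    "enzymatic": frozenset({"k_cat", "K_ms", "K_mp", "K_eq"}),
    "non_enzymatic": frozenset({"k_f", "k_r", "K_eq"}),
    "transport": frozenset({"K_ms"}),
    "degradation": frozenset({"k_deg"}),
    "substrate_release": frozenset(),
    "protein_induction": frozenset(),
}

#: default initial concentration of a metabolite pool, mM
METABOLITE_FLOOR_MM = 1e-28


class NetworkError(ValueError):
    """Raised on catalogue parse or validation failures."""


@dataclass(frozen=True)
class Compartment:
    id: str
    volume_l: float

    def __post_init__(self) -> None:
        if not self.volume_l > 0:
            raise NetworkError(f"compartment {self.id!r}: volume must be > 0")


@dataclass(frozen=True)
class Species:
    """A metabolite, enzyme, transporter or source pool in one compartment."""

    id: str
    compartment: str
    role: str = "metabolite"
    name: str = ""
    initial_concentration: float = METABOLITE_FLOOR_MM  # mM

    def __post_init__(self) -> None:
        if self.role not in SPECIES_ROLES:
            raise NetworkError(f"species {self.id!r}: unknown role {self.role!r}")
        if self.initial_concentration < 0:
            raise NetworkError(f"species {self.id!r}: negative initial concentration")

    @property
    def ref(self) -> str:
        return species_ref(self.id, self.compartment)


def species_ref(species_id: str, compartment: str) -> str:
    """Qualified reference ``id@compartment`` used in reaction rows."""
    return f"{species_id}@{compartment}"


def parse_ref(ref: str) -> tuple[str, str]:
    sid, sep, comp = ref.rpartition("@")
    if not sep or not sid or not comp:
        raise NetworkError(f"malformed species reference {ref!r}")
    return sid, comp


@dataclass(frozen=True)
class ReactionSpec:
    """One numbered reaction.

    ``substrates``/``products`` are tuples of ``(species ref, stoichiometry)``;
    ``catalyst`` is a species ref (enzyme or transporter) or ``None``;
    ``competitors`` are species refs that share this reaction's catalyst;
    ``parameters`` lists the parameter *kinds* this reaction draws.
    """

    number: int
    rtype: str
    substrates: tuple[tuple[str, float], ...] = ()
    products: tuple[tuple[str, float], ...] = ()
    catalyst: str | None = None
    competitors: tuple[str, ...] = ()
    parameters: tuple[str, ...] = ()
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.rtype not in REACTION_TYPES:
            raise NetworkError(f"reaction {self.number}: unknown type {self.rtype!r}")
        for kind in self.parameters:
            if kind not in PARAMETER_KINDS:
                raise NetworkError(
                    f"reaction {self.number}: unknown parameter kind {kind!r}"
                )

    def parameter_name(self, kind: str) -> str:
        """Canonical prior name for one of this reaction's parameter kinds."""
        return f"{kind}_r{self.number}"


def enzyme_conc_name(species_id: str) -> str:
    """Canonical prior name for an enzyme/transporter starting concentration."""
    return f"enzyme_conc_0_{species_id}"


def transporter_kcat_name(species_id: str) -> str:
    """Canonical prior name for a transporter's shared turnover number."""
    return f"k_cat_{species_id}"


@dataclass
class Network:
    name: str
    compartments: dict[str, Compartment]
    species: dict[str, Species]  # keyed by qualified ref
    reactions: dict[int, ReactionSpec] = field(default_factory=dict)

    # -- convenience views -------------------------------------------------
    def metabolites(self) -> list[Species]:
        return [s for s in self.species.values() if s.role == "metabolite"]

    def catalysts(self) -> list[Species]:
        return [s for s in self.species.values() if s.role in ("enzyme", "transporter")]

    def enabled_reactions(self) -> list[ReactionSpec]:
        return [r for r in sorted(self.reactions.values(), key=lambda r: r.number) if r.enabled]

    def sorted_reactions(self) -> list[ReactionSpec]:
        return sorted(self.reactions.values(), key=lambda r: r.number)

    def get_species(self, ref: str) -> Species:
        try:
            return self.species[ref]
        except KeyError:
            raise NetworkError(f"unknown species reference {ref!r}") from None

    def with_reaction_enabled(self, number: int, enabled: bool) -> "Network":
        """Copy of the network with one reaction toggled."""
        if number not in self.reactions:
            raise NetworkError(f"no reaction numbered {number}")
        reactions = dict(self.reactions)
        reactions[number] = replace(reactions[number], enabled=enabled)
        return Network(self.name, dict(self.compartments), dict(self.species), reactions)

    # -- parameter bookkeeping --------------------------------------------
    def required_parameter_names(self, include_disabled: bool = True) -> list[str]:
        """All prior names the network references, catalyst concentrations last.

        Enzyme/transporter concentrations are shared across the reactions a
        catalyst serves and therefore counted once per catalyst species.
        """
        names: list[str] = []
        seen: set[str] = set()
        rxns = self.sorted_reactions() if include_disabled else self.enabled_reactions()
        for rxn in rxns:
            for kind in rxn.parameters:
                if kind == "enzyme_conc_0":
                    continue
                nm = rxn.parameter_name(kind)
                if nm not in seen:
                    seen.add(nm)
                    names.append(nm)
        cats: set[str] = set()
        transporters: set[str] = set()
        for rxn in rxns:
            if rxn.catalyst is not None:
                cid = parse_ref(rxn.catalyst)[0]
                cats.add(cid)
                if rxn.rtype == "transport":
                    transporters.add(cid)
        for tid in sorted(transporters):
            names.append(transporter_kcat_name(tid))
        for cid in sorted(cats):
            names.append(enzyme_conc_name(cid))
        return names


# ---------------------------------------------------------------------------
# validation

def _check_reaction(net: Network, rxn: ReactionSpec, report: list[str]) -> None:
    refs = [r for r, _ in rxn.substrates] + [r for r, _ in rxn.products]
    if rxn.catalyst:
        refs.append(rxn.catalyst)
    refs.extend(rxn.competitors)
    for ref in refs:
        try:
            parse_ref(ref)
        except NetworkError:
            report.append(f"reaction {rxn.number}: malformed reference {ref!r}")
            return
        if ref not in net.species:
            report.append(f"reaction {rxn.number}: unknown species {ref!r}")
            return

    kinds = set(rxn.parameters)
    if rxn.rtype == "enzymatic":
        if kinds != {"k_cat", "K_ms", "K_mp", "K_eq"}:
            report.append(
                f"reaction {rxn.number}: enzymatic reactions draw exactly "
                f"(k_cat, K_ms, K_mp, K_eq), got {sorted(kinds)}"
            )
        if rxn.catalyst is None:
            report.append(f"reaction {rxn.number}: enzymatic reaction lacks a catalyst")
    elif rxn.rtype == "non_enzymatic":
        if kinds != {"k_f", "k_r", "K_eq"}:
            report.append(
                f"reaction {rxn.number}: non-enzymatic reactions draw exactly "
                f"(k_f, k_r, K_eq), got {sorted(kinds)}"
            )
    elif rxn.rtype == "transport":
        if kinds != {"K_ms"}:
            report.append(
                f"reaction {rxn.number}: transport reactions draw exactly (K_ms), "
                f"got {sorted(kinds)}"
            )
        if rxn.catalyst is None:
            report.append(f"reaction {rxn.number}: transport reaction lacks a transporter")
        if len(rxn.substrates) != 1 or len(rxn.products) != 1:
            report.append(f"reaction {rxn.number}: transport must move exactly one species")
        else:
            (sref, _), (pref, _) = rxn.substrates[0], rxn.products[0]
            sid, scomp = parse_ref(sref)
            pid, pcomp = parse_ref(pref)
            if sid != pid:
                report.append(
                    f"reaction {rxn.number}: transport must connect the same chemical "
                    f"identity, got {sid!r} -> {pid!r}"
                )
            if scomp == pcomp:
                report.append(
                    f"reaction {rxn.number}: transport species share compartment {scomp!r}"
                )
    elif rxn.rtype == "degradation":
        if "k_deg" not in kinds:
            report.append(f"reaction {rxn.number}: degradation reaction lacks k_deg")

    if rxn.catalyst is not None:
        cat = net.species.get(rxn.catalyst)
        if cat is not None and cat.role not in ("enzyme", "transporter"):
            report.append(
                f"reaction {rxn.number}: catalyst {rxn.catalyst!r} has role {cat.role!r}"
            )
    # competitors must be substrates of some reaction sharing this catalyst
    if rxn.competitors and rxn.catalyst is None:
        report.append(f"reaction {rxn.number}: competitors listed without a catalyst")
    elif rxn.competitors:
        peers = [
            r
            for r in net.reactions.values()
            if r.catalyst == rxn.catalyst and r.number != rxn.number
        ]
        peer_subs = {ref for r in peers for ref, _ in r.substrates}
        for comp in rxn.competitors:
            if comp not in peer_subs:
                report.append(
                    f"reaction {rxn.number}: competitor {comp!r} is not a substrate of "
                    f"any other reaction catalysed by {rxn.catalyst!r}"
                )


def validate_network(net: Network, prior_names: Iterable[str] | None = None) -> list[str]:
    """Return a list of invariant violations (empty iff the network is valid).

    If ``prior_names`` is given, also flags parameters the network references
    without a matching prior (dangling parameter references).
    """
    report: list[str] = []
    for comp in net.compartments.values():
        if not comp.volume_l > 0:
            report.append(f"compartment {comp.id}: non-positive volume")
    for sp in net.species.values():
        if sp.compartment not in net.compartments:
            report.append(f"species {sp.ref}: unknown compartment {sp.compartment!r}")
        if sp.initial_concentration < 0:
            report.append(f"species {sp.ref}: negative initial concentration")
    for rxn in net.sorted_reactions():
        _check_reaction(net, rxn, report)
    if prior_names is not None:
        have = set(prior_names)
        for nm in net.required_parameter_names():
            if nm not in have:
                report.append(f"dangling parameter reference {nm!r}")
    return report


# ---------------------------------------------------------------------------
# catalogue IO

_SPECIES_COLS = ["compartment", "id", "name", "role", "initial_conc_mM"]
_REACTION_COLS = [
    "number",
    "rtype",
    "substrates",
    "products",
    "catalyst",
    "competitors",
    "parameters",
    "enabled",
]


def _fmt_side(side: tuple[tuple[str, float], ...]) -> str:
    parts = []
    for ref, stoich in side:
        parts.append(ref if stoich == 1 else f"{stoich:g}*{ref}")
    return ";".join(parts)


def _parse_side(text: str, number: int) -> tuple[tuple[str, float], ...]:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        if "*" in part:
            coef, _, ref = part.partition("*")
            try:
                stoich = float(coef)
            except ValueError:
                raise NetworkError(
                    f"reaction {number}: malformed stoichiometry {part!r}"
                ) from None
        else:
            ref, stoich = part, 1.0
        out.append((ref.strip(), stoich))
    return tuple(out)


def save_network(net: Network, path: str | Path) -> Path:
    """Write the catalogue directory (manifest.yaml, species.tsv, reactions.tsv)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "name": net.name,
        "compartments": [
            {"id": c.id, "volume_l": c.volume_l} for c in net.compartments.values()
        ],
        "species_file": "species.tsv",
        "reactions_file": "reactions.tsv",
    }
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    with open(path / "species.tsv", "w", newline="") as fh:
        w = csv.writer(fh, dialect="excel-tab")
        w.writerow(_SPECIES_COLS)
        for sp in sorted(net.species.values(), key=lambda s: (s.compartment, s.id)):
            w.writerow([sp.compartment, sp.id, sp.name, sp.role,
                        repr(sp.initial_concentration)])

    with open(path / "reactions.tsv", "w", newline="") as fh:
        w = csv.writer(fh, dialect="excel-tab")
        w.writerow(_REACTION_COLS)
        for rxn in net.sorted_reactions():
            w.writerow([
                rxn.number,
                rxn.rtype,
                _fmt_side(rxn.substrates),
                _fmt_side(rxn.products),
                rxn.catalyst or "",
                ";".join(rxn.competitors),
                ";".join(rxn.parameters),
                "1" if rxn.enabled else "0",
            ])
    return path


def load_network(path: str | Path, validate: bool = True) -> Network:
    """Load and validate a catalogue directory (or its manifest.yaml)."""
    path = Path(path)
    if path.is_file():
        manifest_path, base = path, path.parent
    else:
        manifest_path, base = path / "manifest.yaml", path
    if not manifest_path.exists():
        raise NetworkError(f"no manifest at {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    compartments = {
        c["id"]: Compartment(c["id"], float(c["volume_l"]))
        for c in manifest["compartments"]
    }

    species: dict[str, Species] = {}
    with open(base / manifest["species_file"], newline="") as fh:
        rdr = csv.DictReader(fh, dialect="excel-tab")
        for i, row in enumerate(rdr, start=2):
            try:
                sp = Species(
                    id=row["id"],
                    compartment=row["compartment"],
                    role=row["role"],
                    name=row.get("name", ""),
                    initial_concentration=float(row["initial_conc_mM"]),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise NetworkError(f"species.tsv line {i}: {exc}") from None
            if sp.ref in species:
                raise NetworkError(f"species.tsv line {i}: duplicate species {sp.ref!r}")
            species[sp.ref] = sp

    reactions: dict[int, ReactionSpec] = {}
    with open(base / manifest["reactions_file"], newline="") as fh:
        rdr = csv.DictReader(fh, dialect="excel-tab")
        for i, row in enumerate(rdr, start=2):
            try:
                number = int(row["number"])
                rxn = ReactionSpec(
                    number=number,
                    rtype=row["rtype"],
                    substrates=_parse_side(row["substrates"], number),
                    products=_parse_side(row["products"], number),
                    catalyst=row["catalyst"] or None,
                    competitors=tuple(p for p in row["competitors"].split(";") if p),
                    parameters=tuple(p for p in row["parameters"].split(";") if p),
                    enabled=row["enabled"].strip() not in ("0", "false", "False", ""),
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise NetworkError(f"reactions.tsv line {i}: {exc}") from None
            if rxn.number in reactions:
                raise NetworkError(f"reactions.tsv line {i}: duplicate reaction {rxn.number}")
            reactions[rxn.number] = rxn

    net = Network(manifest.get("name", base.name), compartments, species, reactions)
    if validate:
        problems = validate_network(net)
        if problems:
            raise NetworkError("invalid catalogue:\n  " + "\n  ".join(problems))
    return net


def networks_equal(a: Network, b: Network) -> bool:
    """Field-by-field equality used by the round-trip contract."""
    if a.name != b.name or a.compartments != b.compartments:
        return False
    if set(a.species) != set(b.species):
        return False
    for ref, sp in a.species.items():
        other = b.species[ref]
        if (sp.id, sp.compartment, sp.role, sp.name) != (
            other.id, other.compartment, other.role, other.name
        ):
            return False
        if not math.isclose(sp.initial_concentration, other.initial_concentration,
                            rel_tol=0, abs_tol=0):
            return False
    return a.reactions == b.reactions
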