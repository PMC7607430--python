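"""Symbol tables: monosaccharides, modifications, and dialect symbol maps.

Every other module resolves saccharide codes through a :class:`Registry`.
The default registry carries the common Linear Code monosaccharide and
modification tables; an "abstract" profile registers the bare letters A-Z
used in schematic examples (theoretical glycans with no linkage data).
Registries are user-extensible at runtime so project-specific sugars can be
added without touching library code.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from .errors import RegistryError

#: Anomers recognized in glycosidic linkages ("?" = unknown).
ANOMERS = ("a", "b", "?")

#: Sentinel Linear Code for a completely unknown saccharide unit.
UNKNOWN_SU = "*"

#: Placeholder for an unknown monosaccharide identity inside a partly known SU.
UNKNOWN_MS = "?"


@dataclass(frozen=True)
class MonosaccharideEntry:
    """One monosaccharide: its Linear Code, IUPAC name, and chemistry defaults.

    ``anomeric_carbon`` is the residue's own linking carbon (1 for aldoses;
    2 for the sialic acids, KDN, Kdo and fructose), used when rendering
    IUPAC-condensed linkages such as ``Neu5Ac(a2-3)``.
    """

    lc_code: str
    iupac_name: str
    anomeric_carbon: int = 1
    default_ring: str = "pyranose"  # "pyranose" | "furanose"
    default_stereo: str = "D"  # "D" | "L"

    def __post_init__(self):
        if not self.lc_code or not (self.lc_code.isalpha() and self.lc_code.isupper()):
            raise RegistryError(f"invalid monosaccharide code {self.lc_code!r}")


@dataclass(frozen=True)
class ModificationEntry:
    lc_code: str
    iupac_name: str


@dataclass(frozen=True)
class SymbolMap:
    """One Table-of-symbols row: a role with its legacy and consensus glyphs."""

    role: str
    legacy_symbol: str
    licorr_symbol: str


# ---------------------------------------------------------------------------
# Default tables
# ---------------------------------------------------------------------------

# (lc, iupac, anomeric carbon, ring, stereo)
_DEFAULT_MONOSACCHARIDES = [
    ("G", "Glc", 1, "pyranose", "D"),     # D-glucose
    ("A", "Gal", 1, "pyranose", "D"),     # D-galactose
    ("GN", "GlcNAc", 1, "pyranose", "D"),
    ("AN", "GalNAc", 1, "pyranose", "D"),
    ("M", "Man", 1, "pyranose", "D"),
    ("NN", "Neu5Ac", 2, "pyranose", "D"),
    ("NG", "Neu5Gc", 2, "pyranose", "D"),
    ("N", "Neu", 2, "pyranose", "D"),
    ("K", "KDN", 2, "pyranose", "D"),
    ("W", "Kdo", 2, "pyranose", "D"),
    ("L", "GalA", 1, "pyranose", "D"),
    ("I", "IdoA", 1, "pyranose", "L"),
    ("H", "Rha", 1, "pyranose", "L"),
    ("F", "Fuc", 1, "pyranose", "L"),
    ("X", "Xyl", 1, "pyranose", "D"),
    ("B", "Rib", 1, "pyranose", "D"),
    ("R", "Araf", 1, "furanose", "L"),
    ("U", "GlcA", 1, "pyranose", "D"),
    ("O", "All", 1, "pyranose", "D"),
    ("P", "Api", 1, "pyranose", "D"),
    ("E", "Fruf", 2, "furanose", "D"),
    ("C", "Asc", 1, "pyranose", "L"),     # ascarylose
    ("T", "Rbo", 1, "pyranose", "D"),     # ribitol
]

_DEFAULT_MODIFICATIONS = [
    ("Q", "N"),      # deacetylated N-acetyl
    ("PE", "Pe"),    # phosphoethanolamine
    ("IN", "In"),    # inositol
    ("ME", "Me"),    # methyl
    ("N", "NAc"),    # N-acetyl
    ("T", "Ac"),     # O-acetyl
    ("P", "P"),      # phosphate
    ("PC", "Pc"),    # phosphocholine
    ("PYR", "Pyr"),  # pyruvate
    ("S", "S"),      # sulfate
    ("SH", "Sh"),    # sulfide
    ("EP", "Ep"),    # aminoethylphosphonate
    ("D", "d"),      # deoxy
    ("CA", "-oic"),  # carboxylic acid
    ("A", "-amine"),
    ("AO", "-amide"),
    ("K", "-one"),   # ketone
]

# Consensus symbol map: legacy (reaction-rule literature) glyph vs LiCoRR glyph.
_DEFAULT_SYMBOL_MAPS = [
    SymbolMap("negation", "~", "!"),
    SymbolMap("and", "&", "&"),
    SymbolMap("or", "or", "or"),
    SymbolMap("continuation", "_", "_"),
    SymbolMap("ligand", "...", "..."),
    SymbolMap("branch", "|", "+"),
    SymbolMap("site", "*", "@"),
    SymbolMap("possible_mod", "$", "$"),
    SymbolMap("count", "#", "n"),
    SymbolMap("fragment_divider", "|", "|"),
    SymbolMap("omission", "*", "*"),
    SymbolMap("conjugate_sep", ";:#", ";:#"),
    SymbolMap("stereo_ring", "~", "~"),
]

#: Alternate spellings accepted on read (IUPAC name -> canonical IUPAC name).
IUPAC_ALIASES = {"Kdn": "KDN", "Rib-ol": "Rbo"}


class Registry:
    """Mutable lookup tables with maximal-munch tokenization support.

    Monosaccharide codes may be 1-2+ uppercase letters; ``codes_by_length``
    yields them longest first so "NN" always lexes as one sialic acid and
    never as two Neu residues.
    """

    def __init__(
        self,
        monosaccharides: list[MonosaccharideEntry],
        modifications: list[ModificationEntry],
        symbol_maps: list[SymbolMap] | None = None,
    ):
        self._ms: dict[str, MonosaccharideEntry] = {}
        self._mods: dict[str, ModificationEntry] = {}
        self.symbol_maps = list(symbol_maps or _DEFAULT_SYMBOL_MAPS)
        for m in monosaccharides:
            self.register_monosaccharide(m)
        for m in modifications:
            if m.lc_code in self._mods:
                raise RegistryError(f"duplicate modification code {m.lc_code!r}")
            self._mods[m.lc_code] = m
        self._refresh()

    # -- lookup -------------------------------------------------------------

    def monosaccharide(self, lc_code: str) -> MonosaccharideEntry:
        try:
            return self._ms[lc_code]
        except KeyError:
            raise RegistryError(f"unknown monosaccharide code {lc_code!r}") from None

    def modification(self, lc_code: str) -> ModificationEntry:
        try:
            return self._mods[lc_code]
        except KeyError:
            raise RegistryError(f"unknown modification code {lc_code!r}") from None

    def has_monosaccharide(self, lc_code: str) -> bool:
        return lc_code in self._ms

    def by_iupac(self, iupac_name: str) -> MonosaccharideEntry:
        name = IUPAC_ALIASES.get(iupac_name, iupac_name)
        for entry in self._ms.values():
            if entry.iupac_name == name:
                return entry
        raise RegistryError(f"no monosaccharide with IUPAC name {iupac_name!r}")

    def modification_by_iupac(self, iupac_name: str) -> ModificationEntry:
        for entry in self._mods.values():
            if entry.iupac_name == iupac_name:
                return entry
        raise RegistryError(f"no modification with IUPAC name {iupac_name!r}")

    def symbol(self, role: str, dialect: str) -> str:
        for sm in self.symbol_maps:
            if sm.role == role:
                return sm.licorr_symbol if dialect == "licorr" else sm.legacy_symbol
        raise RegistryError(f"unknown symbol role {role!r}")

    @property
    def monosaccharides(self) -> list[MonosaccharideEntry]:
        return list(self._ms.values())

    @property
    def modifications(self) -> list[ModificationEntry]:
        return list(self._mods.values())

    # -- mutation -----------------------------------------------------------

    def register_monosaccharide(
        self, entry: MonosaccharideEntry, overwrite: bool = False
    ) -> "Registry":
        if entry.lc_code in self._ms and not overwrite:
            raise RegistryError(
                f"monosaccharide code {entry.lc_code!r} already registered"
            )
        self._ms[entry.lc_code] = entry
        self._refresh()
        return self

    def _refresh(self):
        # longest-match order for the tokenizer
        self.codes_by_length = sorted(self._ms, key=len, reverse=True)
        self.mod_codes_by_length = sorted(self._mods, key=len, reverse=True)

    # -- construction helpers ----------------------------------------------

    def copy(self) -> "Registry":
        return Registry(self.monosaccharides, self.modifications, self.symbol_maps)


def default_registry() -> Registry:
    """The standard tables: 23 monosaccharides, 17 modifications, 13 symbol rows."""
    return Registry(
        [MonosaccharideEntry(*row) for row in _DEFAULT_MONOSACCHARIDES],
        [ModificationEntry(*row) for row in _DEFAULT_MODIFICATIONS],
        list(_DEFAULT_SYMBOL_MAPS),
    )


def abstract_registry() -> Registry:
    """Single letters A-Z as abstract monosaccharides (schematic glycans).

    Used for theoretical examples like ``E(D(C)B)A`` where letters stand for
    arbitrary residues and carry no linkage information. Modifications and
    symbol maps are the defaults.
    """
    entries = [
        MonosaccharideEntry(chr(c), f"Abs{chr(c)}") for c in range(ord("A"), ord("Z") + 1)
    ]
    return Registry(
        entries,
        [ModificationEntry(*row) for row in _DEFAULT_MODIFICATIONS],
        list(_DEFAULT_SYMBOL_MAPS),
    )


def load_registry_tsv(stream: io.TextIOBase) -> Registry:
    """Read a registry override file.

    Columns (tab-separated, header required):
    ``lc_code  iupac_name  anomeric_carbon  ring  stereo``.
    """
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    header = lines[0].split("\t")
    required = ["lc_code", "iupac_name", "anomeric_carbon", "ring", "stereo"]
    if [h.strip() for h in header[:5]] != required:
        raise RegistryError(f"registry file must have columns {required}")
    entries = []
    for ln in lines[1:]:
        code, name, ac, ring, stereo = (f.strip() for f in ln.split("\t")[:5])
        entries.append(MonosaccharideEntry(code, name, int(ac), ring, stereo))
    return Registry(entries, [ModificationEntry(*row) for row in _DEFAULT_MODIFICATIONS])


def default_tables():
    """Return the raw default tables (monosaccharides, modifications, symbol maps)."""
    reg = default_registry()
    return reg.monosaccharides, reg.modifications, reg.symbol_maps


__all__ = [
    "ANOMERS",
    "UNKNOWN_SU",
    "UNKNOWN_MS",
    "MonosaccharideEntry",
    "ModificationEntry",
    "SymbolMap",
    "Registry",
    "default_registry",
    "abstract_registry",
    "default_tables",
    "load_registry_tsv",
]
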