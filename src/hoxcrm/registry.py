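"""Fixed biological constants: Hox factors, Hox–Exd specificity classes, core
sequences, composite-site architecture, and segment expression domains.

The three Hox–Exd latent-specificity classes are defined by the preferred
8-bp core recognised by the Hox–Exd complex:

======  ==========  ==========================
class   core        member factors
======  ==========  ==========================
class1  TGATTGAT    Lab, Pb
class2  TGATTAAT    Dfd, Scr
class3  TGATTTAT    Antp, Ubx, Abd-A, Abd-B
======  ==========  ==========================

The cores differ only at core index 5 (G/A/T).  Hox monomers, by contrast,
share a short TAAT core (Abd-B prefers TTAT or TTAG) inside a ~6-bp
footprint; cofactor complex formation widens the recognition site to ~12 bp
(one Exd-side flank base, the 8-bp core, three Hox-side flank bases).

Segment naming runs anterior to posterior: intercalary (ic), mandible (md),
maxilla (mx), labium (lb), three thoracic (T1–T3) and nine abdominal
(A1–A9) segments.  The per-factor ``expression_segments`` are the
*activation domains used by the expression model*: the domains in which a
factor's removal abolishes target activation (Lab ic; Dfd md/mx; Scr lb/T1;
Antp T1–T3; Ubx T3–A1; Abd-A A2–A7; Abd-B A8–A9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .seqs import SequenceError, check_dna, revcomp

CLASS_LABELS = ("class1", "class2", "class3")

GENERIC_MONOMER_CORE = "TAAT"
ABDB_MONOMER_CORES = ("TTAT", "TTAG")
MONOMER_FOOTPRINT = 6  #: short AT-rich monomer recognition element

DIMER_TEMPLATE = "NTGATTAATNNN"  #: canonical ~12-bp Hox–Exd site layout


class RegistryError(KeyError):
    """Unknown class label, factor or segment."""


@dataclass(frozen=True)
class HoxClass:
    label: str
    core: str
    member_factors: tuple[str, ...]

    def __post_init__(self) -> None:
        core = check_dna(self.core, name=f"{self.label} core")
        if len(core) != 8:
            raise SequenceError(f"class core must be 8 bp, got {len(core)}")
        object.__setattr__(self, "core", core)


@dataclass(frozen=True)
class HoxFactor:
    name: str
    hox_class: str  # class label or "none" for cofactors
    expression_segments: tuple[str, ...]
    monomer_competence: float = 0.3


@dataclass(frozen=True)
class SiteArchitecture:
    """Positional layout of a composite Hox–Exd site window.

    ``template`` uses N for flank wildcard positions; index sets are template
    indices (0-based).  The default is the 12-bp layout with the Exd-side
    flank at index 0, the 8-bp core at 1–8 and Hox-side flanks at 9–11.
    """

    template: str = DIMER_TEMPLATE
    core_positions: tuple[int, ...] = tuple(range(1, 9))
    exd_flank_positions: tuple[int, ...] = (0,)
    hox_flank_positions: tuple[int, ...] = (9, 10, 11)

    def __post_init__(self) -> None:
        core = set(self.core_positions)
        flanks = set(self.exd_flank_positions) | set(self.hox_flank_positions)
        if core & flanks:
            raise ValueError("flank positions must be disjoint from core positions")
        if core | flanks != set(range(len(self.template))):
            raise ValueError("core + flank positions must tile the template")

    @property
    def footprint(self) -> int:
        return len(self.template)

    def core_of(self, window: str) -> str:
        """Extract the core substring from a full window."""
        return "".join(window[i] for i in self.core_positions)

    @property
    def flank_positions(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.exd_flank_positions) | set(self.hox_flank_positions)))


#: monomer window layout: one flank base, the 4-bp core, one flank base
MONOMER_ARCHITECTURE = SiteArchitecture(
    template="NTAATN",
    core_positions=(1, 2, 3, 4),
    exd_flank_positions=(0,),
    hox_flank_positions=(5,),
)

DEFAULT_SEGMENTS = (
    "ic", "md", "mx", "lb",
    "T1", "T2", "T3",
    "A1", "A2", "A3", "A4", "A5", "A6", "A7", "A8", "A9",
)

_DEFAULT_CLASSES = (
    HoxClass("class1", "TGATTGAT", ("Lab", "Pb")),
    HoxClass("class2", "TGATTAAT", ("Dfd", "Scr")),
    HoxClass("class3", "TGATTTAT", ("Antp", "Ubx", "Abd-A", "Abd-B")),
)

_DEFAULT_FACTORS = (
    HoxFactor("Lab", "class1", ("ic",)),
    HoxFactor("Pb", "class1", ()),  # expression domain unused in this system
    HoxFactor("Dfd", "class2", ("md", "mx")),
    HoxFactor("Scr", "class2", ("lb", "T1")),
    HoxFactor("Antp", "class3", ("T1", "T2", "T3")),
    HoxFactor("Ubx", "class3", ("T3", "A1")),
    HoxFactor("Abd-A", "class3", ("A2", "A3", "A4", "A5", "A6", "A7")),
    HoxFactor("Abd-B", "class3", ("A8", "A9"), monomer_competence=1.0),
)


@dataclass
class Registry:
    """Lookup tables for classes, factors and segments."""

    classes: dict[str, HoxClass] = field(
        default_factory=lambda: {c.label: c for c in _DEFAULT_CLASSES}
    )
    factors: dict[str, HoxFactor] = field(
        default_factory=lambda: {f.name: f for f in _DEFAULT_FACTORS}
    )
    segments: tuple[str, ...] = DEFAULT_SEGMENTS
    architecture: SiteArchitecture = field(default_factory=SiteArchitecture)

    def __post_init__(self) -> None:
        for f in self.factors.values():
            unknown = set(f.expression_segments) - set(self.segments)
            if unknown:
                raise RegistryError(f"factor {f.name} lists unknown segments {sorted(unknown)}")
            if f.hox_class != "none" and f.hox_class not in self.classes:
                raise RegistryError(f"factor {f.name} has unknown class {f.hox_class}")

    # -- class taxonomy ----------------------------------------------------
    def class_core(self, label: str) -> str:
        try:
            return self.classes[label].core
        except KeyError:
            raise RegistryError(f"unknown class label {label!r}") from None

    def classify_window(self, window: str) -> str | None:
        """Exact, strand-naive class call for an 8-bp core window."""
        window = check_dna(window, name="window")
        if len(window) != 8:
            raise SequenceError(f"classify_window needs an 8-bp window, got {len(window)}")
        for label, cls in self.classes.items():
            if window == cls.core:
                return label
        return None

    def monomer_cores(self) -> dict[str, tuple[str, ...]]:
        return {"generic": (GENERIC_MONOMER_CORE,), "abdb": ABDB_MONOMER_CORES}

    def monomer_cores_for(self, factor: str) -> tuple[str, ...]:
        if factor == "Abd-B":
            return ABDB_MONOMER_CORES
        return (GENERIC_MONOMER_CORE,)

    # -- segments ----------------------------------------------------------
    def factors_in_segment(self, segment: str) -> list[str]:
        if segment not in self.segments:
            raise RegistryError(f"unknown segment {segment!r}")
        return [f.name for f in self.factors.values() if segment in f.expression_segments]

    def hox_factor_names(self) -> list[str]:
        return [f.name for f in self.factors.values() if f.hox_class != "none"]

    def core_motifs(self, include_monomer: bool = False) -> dict[str, str]:
        """Named exact core motifs, for scanning and forbidden-motif lists."""
        motifs = {label: cls.core for label, cls in self.classes.items()}
        if include_monomer:
            motifs["monomer"] = GENERIC_MONOMER_CORE
            motifs["monomer_abdb_ttat"] = ABDB_MONOMER_CORES[0]
            motifs["monomer_abdb_ttag"] = ABDB_MONOMER_CORES[1]
        return motifs

    def forbidden_background_motifs(self) -> list[str]:
        """Motifs to exclude from neutral backgrounds on either strand.

        Closing the set under reverse complement lets a single plus-strand
        scan guarantee both strands are clean.
        """
        motifs = set()
        for core in list(self.core_motifs(include_monomer=True).values()):
            motifs.add(core)
            motifs.add(revcomp(core))
        return sorted(motifs)

    # -- config round trip -------------------------------------------------
    def to_config(self) -> dict:
        return {
            "segments": list(self.segments),
            "classes": [
                {"label": c.label, "core": c.core, "member_factors": list(c.member_factors)}
                for c in self.classes.values()
            ],
            "factors": [
                {
                    "name": f.name,
                    "hox_class": f.hox_class,
                    "expression_segments": list(f.expression_segments),
                    "monomer_competence": f.monomer_competence,
                }
                for f in self.factors.values()
            ],
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "Registry":
        return cls(
            classes={
                c["label"]: HoxClass(c["label"], c["core"], tuple(c["member_factors"]))
                for c in cfg["classes"]
            },
            factors={
                f["name"]: HoxFactor(
                    f["name"],
                    f["hox_class"],
                    tuple(f["expression_segments"]),
                    float(f.get("monomer_competence", 0.3)),
                )
                for f in cfg["factors"]
            },
            segments=tuple(cfg["segments"]),
        )

    def write_config(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def read_config(cls, path) -> "Registry":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


def default_registry() -> Registry:
    return Registry()
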