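"""Synthetic inputs with recorded ground truth for every pipeline stage.

Four generators emulate the data classes the analysis consumes:

* multi-species cadherin ectodomain families with controllable repeat
  counts, per-junction linker classes (canonical / noncanonical /
  degenerate), per-site substitution rate and invariant-site fraction;
* toy sphere-atom structures (two-chain overlapping spheres with
  closed-form SASA/interface areas, placed calcium sites, disulfide pairs,
  tilted two-domain rods);
* bead-field micrographs of non-overlapping rendered disks;
* noisy 1:1-binding sensorgram injection series (delegates to
  binding_kinetics.simulate_sensorgram).

Every generator is deterministic under a fixed seed and emits
machine-readable ground truth alongside the data.  Idealizations are
deliberate: substitution is uniform over a reduced residue alphabet that
excludes D, E, N, P and C outside designed motif cassettes, so that repeat
boundaries, linker classes, sequons and disulfides admit exact round-trip
checks (no spurious motif matches); there are no indels and no
phylogenetic rate structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import binding_kinetics
from .sequence_annotation import ProteinRecord
from .structure_analysis import (
    Atom,
    Chain,
    Residue,
    StructureModel,
    two_sphere_interface_area,
    two_sphere_sasa,
)

__all__ = [
    "FamilyConfig",
    "FamilyGroundTruth",
    "ConfigInvalid",
    "generate_family",
    "ToyStructureConfig",
    "generate_toy_structure",
    "toy_two_sphere_model",
    "toy_calcium_model",
    "toy_disulfide_model",
    "toy_rod_domains",
    "write_pdb",
    "generate_bead_field",
    "generate_sensorgram_set",
]

# residues allowed at unconstrained positions: no D/E (acidic), no N/P
# (boundary & sequon letters), no C (disulfides) -> motif ground truth exact
NEUTRAL_ALPHABET = "AFGHIKLMQRSTVWY"

LINKER_CLASSES = ("canonical", "noncanonical", "degenerate")
CALCIUM_BY_CLASS = {"canonical": 3, "noncanonical": 2, "degenerate": 0}

# 25-residue repeat-tail cassette: XEX .. DXD .. DRD .. XDX .. DXNDN
# (element, spacer, element, ... boundary), all protected from mutation.
_CASSETTES = {
    "canonical": ("IEL", "DAD", "DRE", "LDV", "DVNDN"),
    "noncanonical": ("SYN", "DAD", "DRE", "LDV", "DMPDL"),
    "degenerate": ("STA", "GSA", "KLA", "TVA", "GSAKL"),
}
_SPACER = "GT"


class ConfigInvalid(ValueError):
    pass


@dataclass
class FamilyConfig:
    repeat_count: int = 3
    repeat_length_range: tuple = (95, 110)
    linker_classes: Optional[Sequence[str]] = None  # per junction; default canonical
    species_count: int = 5
    substitution_rate: float = 0.1
    invariant_fraction: float = 0.1
    n_sequons: int = 0
    disulfide_in_repeat1: bool = False
    site0: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repeat_count < 1 or self.species_count < 1:
            raise ConfigInvalid("repeat_count and species_count must be >= 1")
        if not (0.0 <= self.substitution_rate <= 1.0):
            raise ConfigInvalid("substitution_rate must be in [0, 1]")
        if not (0.0 <= self.invariant_fraction <= 1.0):
            raise ConfigInvalid("invariant_fraction must be in [0, 1]")
        lo, hi = self.repeat_length_range
        if lo < 60 or hi < lo:
            raise ConfigInvalid("repeat lengths must satisfy 60 <= lo <= hi")
        if self.linker_classes is not None:
            if len(self.linker_classes) != self.repeat_count - 1:
                raise ConfigInvalid("one linker class per junction expected")
            bad = set(self.linker_classes) - set(LINKER_CLASSES)
            if bad:
                raise ConfigInvalid(f"unknown linker classes {sorted(bad)}")
        if self.site0 and lo < 105:
            raise ConfigInvalid(
                "site0 cassette needs repeat lengths >= 105 so the XDX-top "
                "element stays clear of the junction window"
            )


@dataclass
class FamilyGroundTruth:
    boundaries: list  # 1-based end position of each internal repeat
    repeat_spans: list  # (start, end) per repeat
    linker_classes: list
    calcium_counts: list
    sequon_positions: list
    disulfide_pairs: list
    invariant_sites: list  # 1-based positions protected in all species
    protected_sites: list  # all mutation-protected positions (motifs + invariant)
    identity_matrix: np.ndarray  # realized percent identity, recounted


def _build_ancestor(cfg: FamilyConfig, rng: np.random.Generator):
    """Ancestor sequence with protected cassette positions recorded."""
    classes = list(cfg.linker_classes) if cfg.linker_classes is not None else [
        "canonical"
    ] * (cfg.repeat_count - 1)
    lo, hi = cfg.repeat_length_range
    protected: set[int] = set()
    seq: list[str] = []
    spans = []
    boundaries = []
    sequon_positions: list[int] = []
    disulfide_pairs: list[tuple] = []

    for rep in range(cfg.repeat_count):
        length = int(rng.integers(lo, hi + 1))
        start = len(seq) + 1
        terminal = rep == cfg.repeat_count - 1
        cassette = None
        if not terminal:
            e1, e2, e3, e4, e5 = _CASSETTES[classes[rep]]
            cassette = e1 + _SPACER + e2 + _SPACER + e3 + _SPACER + e4 + _SPACER + e5
            assert len(cassette) == 25
        body_len = length - (len(cassette) if cassette else 0)
        body = list(rng.choice(list(NEUTRAL_ALPHABET), size=body_len))

        if rep == 0 and cfg.site0:
            body[0] = "N"
            body[31:36] = list("DADAD")
            body[77:80] = list("ADA")
            protected |= {start, *range(start + 31, start + 36),
                          *range(start + 77, start + 80)}
        if rep == 0 and cfg.disulfide_in_repeat1:
            c1, c2 = 5, 73  # A/F-strand-like spacing
            body[c1 - 1] = "C"
            body[c2 - 1] = "C"
            protected |= {start + c1 - 1, start + c2 - 1}
            disulfide_pairs.append((start + c1 - 1, start + c2 - 1))

        seq.extend(body)
        if cassette:
            cas_start = len(seq) + 1
            seq.extend(cassette)
            protected |= set(range(cas_start, cas_start + len(cassette)))
        end = len(seq)
        spans.append((start, end))
        if not terminal:
            boundaries.append(end)

    # seed non-overlapping sequons in repeat interiors (away from cassettes)
    if cfg.n_sequons:
        candidates = [
            p for p in range(1, len(seq) - 2)
            if not ({p, p + 1, p + 2} & protected)
            and all(abs(p - b) > 30 for b in boundaries)
        ]
        rng.shuffle(candidates)
        placed: list[int] = []
        for p in candidates:
            if len(placed) == cfg.n_sequons:
                break
            if any(abs(p - q) < 4 for q in placed):
                continue
            seq[p - 1] = "N"
            seq[p] = str(rng.choice([c for c in NEUTRAL_ALPHABET if c not in "ST"]))
            seq[p + 1] = str(rng.choice(["S", "T"]))
            protected |= {p, p + 1, p + 2}
            placed.append(p)
        sequon_positions = sorted(placed)

    return (
        "".join(seq), spans, boundaries, classes, sequon_positions,
        disulfide_pairs, protected,
    )


def generate_family(cfg: FamilyConfig):
    """Generate a species family from a motif-grammar ancestor.

    Returns (records, FamilyGroundTruth).  Descendants are mutated per
    site at ``substitution_rate`` with motif cassettes and invariant sites
    protected absolutely, so the recorded annotations hold for every
    species.  The realized identity matrix is recounted directly from the
    emitted sequences (positional identity; sequences share length).
    """
    rng = np.random.default_rng(cfg.seed)
    (ancestor, spans, boundaries, classes, sequons, disulfides,
     protected) = _build_ancestor(cfg, rng)
    n = len(ancestor)

    free = [p for p in range(1, n + 1) if p not in protected]
    n_inv = int(round(cfg.invariant_fraction * len(free)))
    invariant = set(
        rng.choice(free, size=n_inv, replace=False).tolist()
    ) if n_inv else set()
    immutable = protected | invariant

    records = []
    seqs = []
    for s in range(cfg.species_count):
        letters = list(ancestor)
        for p in range(1, n + 1):
            if p in immutable:
                continue
            if rng.random() < cfg.substitution_rate:
                current = letters[p - 1]
                choices = [c for c in NEUTRAL_ALPHABET if c != current]
                letters[p - 1] = str(rng.choice(choices))
        seq = "".join(letters)
        seqs.append(seq)
        records.append(ProteinRecord(id=f"sp{s:02d}", species=f"sp{s:02d}", sequence=seq))

    m = cfg.species_count
    idm = np.full((m, m), 100.0)
    for i in range(m):
        for j in range(i + 1, m):
            ident = sum(a == b for a, b in zip(seqs[i], seqs[j])) / n * 100.0
            idm[i, j] = idm[j, i] = ident

    truth = FamilyGroundTruth(
        boundaries=boundaries,
        repeat_spans=spans,
        linker_classes=classes,
        calcium_counts=[CALCIUM_BY_CLASS[c] for c in classes],
        sequon_positions=sequons,
        disulfide_pairs=disulfides,
        invariant_sites=sorted(invariant),
        protected_sites=sorted(immutable),
        identity_matrix=idm,
    )
    return records, truth


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

@dataclass
class ToyStructureConfig:
    # per chain: list of (center xyz, radius, element) sphere atoms
    chains: dict = field(default_factory=dict)
    calcium_positions: Sequence = ()
    coordinating_oxygens: Sequence = ()  # (xyz) protein oxygens
    cysteine_sg_pairs: Sequence = ()  # ((xyz1, xyz2), ...)
    spacegroup: Optional[str] = None
    cell: Optional[tuple] = None

    def validate(self) -> None:
        for cid, atoms in self.chains.items():
            for center, radius, _ in atoms:
                if radius <= 0:
                    raise ConfigInvalid(f"non-positive radius in chain {cid}")
                if not np.all(np.isfinite(center)):
                    raise ConfigInvalid(f"non-finite coordinates in chain {cid}")


def generate_toy_structure(cfg: ToyStructureConfig) -> StructureModel:
    """Build a StructureModel of sphere atoms (one residue per atom),
    appending any calcium ions, coordinating oxygens and SG pairs."""
    cfg.validate()
    chains = []
    for cid, atoms in cfg.chains.items():
        ch = Chain(id=cid)
        for i, (center, radius, element) in enumerate(atoms, start=1):
            res = Residue(name="SPH", seqid=i)
            res.atoms.append(
                Atom(name=element, element=element,
                     coord=np.asarray(center, float), radius=radius)
            )
            ch.residues.append(res)
        chains.append(ch)
    extra = Chain(id="X")
    seq = 1
    for xyz in cfg.coordinating_oxygens:
        res = Residue(name="SER", seqid=seq)
        res.atoms.append(Atom(name="OG", element="O", coord=np.asarray(xyz, float)))
        extra.residues.append(res)
        seq += 1
    for xyz in cfg.calcium_positions:
        res = Residue(name="CA", seqid=seq)
        res.atoms.append(Atom(name="CA", element="CA", coord=np.asarray(xyz, float)))
        extra.residues.append(res)
        seq += 1
    for a, b in cfg.cysteine_sg_pairs:
        for xyz in (a, b):
            res = Residue(name="CYS", seqid=seq)
            res.atoms.append(Atom(name="SG", element="S", coord=np.asarray(xyz, float)))
            extra.residues.append(res)
            seq += 1
    if extra.residues:
        chains.append(extra)
    return StructureModel(chains=chains, spacegroup=cfg.spacegroup, cell=cfg.cell)


def toy_two_sphere_model(
    r1: float = 3.0, r2: float = 3.0, d: float = 5.0
) -> tuple[StructureModel, dict]:
    """Two single-sphere chains at separation ``d`` plus the analytic
    SASA/interface oracle values (probe-expanded cap formulas)."""
    cfg = ToyStructureConfig(
        chains={
            "A": [((0.0, 0.0, 0.0), r1, "C")],
            "B": [((d, 0.0, 0.0), r2, "C")],
        }
    )
    s1, s2 = two_sphere_sasa(r1, r2, d)
    oracle = {
        "sasa_A": s1,
        "sasa_B": s2,
        "interface_area": two_sphere_interface_area(r1, r2, d),
    }
    return generate_toy_structure(cfg), oracle


def toy_calcium_model(n_sites: int = 3, seed: int = 0) -> tuple[StructureModel, list]:
    """``n_sites`` calcium ions, each coordinated by three oxygens at
    2.3-2.5 A; sites separated by 20 A.  Returns the model and the ground
    truth [(ion xyz, [oxygen xyz, ...]), ...]."""
    rng = np.random.default_rng(seed)
    calcium, oxygens, truth = [], [], []
    for k in range(n_sites):
        center = np.array([20.0 * k, 0.0, 0.0])
        calcium.append(center)
        site_ox = []
        for _ in range(3):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            xyz = center + direction * rng.uniform(2.3, 2.5)
            oxygens.append(xyz)
            site_ox.append(xyz)
        truth.append((center, site_ox))
    cfg = ToyStructureConfig(
        chains={"A": [((5.0, 40.0, 0.0), 2.0, "C")]},
        calcium_positions=calcium,
        coordinating_oxygens=oxygens,
    )
    return generate_toy_structure(cfg), truth


def toy_disulfide_model(sg_distance: float = 2.05) -> StructureModel:
    cfg = ToyStructureConfig(
        chains={"A": [((0.0, 20.0, 0.0), 2.0, "C")]},
        cysteine_sg_pairs=(((0.0, 0.0, 0.0), (sg_distance, 0.0, 0.0)),),
    )
    return generate_toy_structure(cfg)


def toy_rod_domains(
    tilt_degrees: float, n_points: int = 20, length: float = 40.0
) -> tuple[np.ndarray, np.ndarray]:
    """Reference rod along z and a partner rod tilted by ``tilt_degrees``
    in the x-z plane; exact principal axes, for the orientation operator."""
    t = np.linspace(-length / 2, length / 2, n_points)
    ref = np.column_stack((np.zeros_like(t), np.zeros_like(t), t))
    rad = np.radians(tilt_degrees)
    axis = np.array([np.sin(rad), 0.0, np.cos(rad)])
    partner = np.outer(t, axis) + np.array([60.0, 0.0, 0.0])
    return ref, partner


def write_pdb(model: StructureModel) -> str:
    """Serialize a StructureModel to minimal PDB text (CRYST1 when
    symmetry is present; HETATM for waters/ions)."""
    lines = []
    if model.cell and model.spacegroup:
        a, b, c, al, be, ga = model.cell
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} "
            f"{model.spacegroup:<11s}"
        )
    serial = 1
    for ch in model.chains:
        for res in ch.residues:
            rec = "HETATM" if res.is_hetero_nonprotein else "ATOM  "
            for atom in res.atoms:
                x, y, z = atom.coord
                name = atom.name[:4]
                lines.append(
                    f"{rec}{serial:5d} {name:<4s} {res.name[:3]:>3s} "
                    f"{ch.id[:1]}{res.seqid:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          "
                    f"{atom.element[:2]:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# bead fields
# ---------------------------------------------------------------------------

def generate_bead_field(
    n_disks: int,
    radius_range: tuple = (5.0, 12.0),
    shape: tuple = (256, 256),
    foreground: float = 200.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    min_gap: float = 3.0,
    max_tries: int = 10000,
):
    """Render ``n_disks`` non-overlapping disks by rejection sampling.

    Returns (image float array, ground truth list of dicts with center,
    radius and the exact rendered pixel area).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, background, float)
    yy, xx = np.mgrid[0:h, 0:w]
    placed = []
    truth = []
    tries = 0
    while len(placed) < n_disks:
        tries += 1
        if tries > max_tries:
            raise ConfigInvalid(
                f"could not place {n_disks} disks in {shape} after {max_tries} tries"
            )
        r = rng.uniform(*radius_range)
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if any(
            np.hypot(cy - py, cx - px) < r + pr + min_gap
            for py, px, pr in placed
        ):
            continue
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
        img[mask] = foreground
        placed.append((cy, cx, r))
        truth.append(
            {"center": (cy, cx), "radius": r, "area_px": int(mask.sum())}
        )
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img, truth


def generate_sensorgram_set(
    kon: float = 1.0e4,
    koff: float = 0.16,
    rmax: float = 100.0,
    concentrations: Sequence[float] = (2e-6, 4e-6, 8e-6, 12e-6, 16e-6, 20e-6, 23.5e-6),
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    **kwargs,
) -> binding_kinetics.Sensorgram:
    """Injection series at the binding regime of the intermicrovillar
    heterophilic bond (KD = koff/kon = 16 uM at the defaults; analyte
    spanning 2-23.5 uM)."""
    return binding_kinetics.simulate_sensorgram(
        kon, koff, rmax, list(concentrations),
        noise_sd=noise_sd, seed=seed, **kwargs,
    )
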