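"""Phosphopeptide-to-structure mapping and interface descriptors.

Given a modified peptide and a protein–protein complex, this module
computes the descriptors used to judge whether the modification site
participates in the binding interface:

``K_SASA``
    Ratio of the peptide's solvent-accessible surface area within the
    full complex to its SASA within its own chain extracted alone.
    Values below 1 mean the partner buries part of the peptide, i.e.
    the peptide sits in (or near) the interface.
``HB`` / ``HP``
    Counts of hydrogen-bond donor–acceptor pairs and apolar
    carbon–carbon contacts between the peptide and the non-peptide
    atoms of the complex.
``location class``
    In / Near / Out, from the mean K_SASA and the minimum heavy-atom
    distance from the peptide to any partner chain.

SASA is computed by Shrake–Rupley sphere sampling over heavy atoms
with Chothia-style radii (C 1.87, N 1.65, O 1.40, S 1.85 A) and a
1.4 A water probe; hydrogens are ignored, waters and ligands excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import StructureModel

__all__ = [
    "ATOM_RADII",
    "PeptideQuery",
    "PeptideMapping",
    "ComplexDescriptors",
    "InterfaceReport",
    "sphere_points",
    "shrake_rupley",
    "sasa",
    "map_peptide",
    "k_sasa",
    "min_partner_distance",
    "count_contacts",
    "classify_location",
    "aggregate_complexes",
]

#: Chothia-style heavy-atom radii, Angstrom. Phosphorus is included so
#: phosphorylated residues and nucleotide ligands do not abort a run.
ATOM_RADII = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80}

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere.

    Golden-section spiral; the classic Shrake–Rupley construction with
    a fixed point set, so results are bit-reproducible.
    """
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    coords: np.ndarray,
    elements,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
    subset=None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, A^2.

    Each atom is expanded by the probe radius and sampled with
    ``n_points`` sphere points; a point is accessible if it lies
    outside every neighbouring expanded sphere. Per-atom values sum to
    the SASA of the structure. ``subset`` restricts the computation to
    the given atom indices (other entries are returned as 0); the
    occluders are always the full coordinate set.

    Raises
    ------
    ValueError
        If an element has no tabulated radius (names the atom).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.empty(len(coords))
    for idx, el in enumerate(elements):
        try:
            radii[idx] = ATOM_RADII[el.upper()]
        except KeyError:
            raise ValueError(
                f"atom {idx} has element {el!r} with no assigned radius"
            ) from None
    ext = radii + probe_radius
    pts = sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.zeros(len(coords))
    targets = range(len(coords)) if subset is None else np.asarray(subset)
    for i in targets:
        neigh = tree.query_ball_point(coords[i], ext[i] + ext.max())
        neigh = [j for j in neigh if j != i
                 and np.linalg.norm(coords[j] - coords[i]) < ext[i] + ext[j]]
        surface = coords[i] + ext[i] * pts
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((surface - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
        out[i] = accessible.mean() * 4.0 * math.pi * ext[i] ** 2
    return out


def sasa(
    atoms: pd.DataFrame,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> pd.Series:
    """SASA per heavy atom of an atom table (hydrogens dropped)."""
    heavy = atoms[atoms["element"].str.upper() != "H"]
    areas = shrake_rupley(
        heavy[["x", "y", "z"]].to_numpy(),
        heavy["element"].tolist(),
        probe_radius=probe_radius,
        n_points=n_points,
    )
    return pd.Series(areas, index=heavy.index)


# ---------------------------------------------------------------------------
# Peptide mapping
# ---------------------------------------------------------------------------

@dataclass
class PeptideQuery:
    """A (possibly phosphorylated) peptide to locate in structures."""

    peptide: str
    mod_sites: list[tuple[int, str]] = field(default_factory=list)
    protein_id: str = ""

    def __post_init__(self) -> None:
        if not self.peptide:
            raise ValueError("empty peptide")
        for pos, mod in self.mod_sites:
            if not 1 <= pos <= len(self.peptide):
                raise ValueError(
                    f"mod site {pos} outside peptide of length "
                    f"{len(self.peptide)}"
                )


@dataclass
class PeptideMapping:
    """One placement of a peptide on a structure chain."""

    structure_id: str
    chain: str
    start: int  # resseq, inclusive
    end: int    # resseq, inclusive
    fraction_resolved: float
    match_mode: str = "exact"

    def __post_init__(self) -> None:
        if not 0.8 <= self.fraction_resolved <= 1.0:
            raise ValueError(
                f"fraction_resolved {self.fraction_resolved} outside [0.8, 1]"
            )


def _gapped_sequence(residues):
    """One-letter string with 'X' for unresolved gaps, plus resseq map."""
    letters: list[str] = []
    info: list[tuple[int, str] | None] = []
    prev = None
    for resseq, icode, one in residues:
        if prev is not None and not icode:
            jump = resseq - prev - 1
            if 0 < jump <= 50:
                letters.extend("X" * jump)
                info.extend([None] * jump)
        letters.append(one)
        info.append((resseq, icode))
        prev = resseq
    return "".join(letters), info


def map_peptide(
    query: PeptideQuery,
    structure: StructureModel,
    il_equivalent: bool = False,
    max_gap_fraction: float = 0.2,
) -> list[PeptideMapping]:
    """Locate a peptide on every chain of a structure.

    Exact substring search against each chain's resolved-residue
    sequence, tolerating internal unresolved gaps up to
    ``max_gap_fraction`` of the peptide length. All matches are
    returned; multiple matches within one chain raise a warning. An
    empty list means the peptide is absent (the caller decides what
    that implies).
    """
    pep = query.peptide.upper()
    if il_equivalent:
        pep_cmp = pep.replace("I", "L")
    else:
        pep_cmp = pep
    n = len(pep)
    hits: list[PeptideMapping] = []
    for chain in structure.chains:
        seq, info = _gapped_sequence(structure.chain_residues[chain])
        cmp_seq = seq.replace("I", "L") if il_equivalent else seq
        chain_hits = 0
        for i in range(len(cmp_seq) - n + 1):
            window = cmp_seq[i:i + n]
            if window[0] == "X" or window[-1] == "X":
                continue
            n_gap = window.count("X")
            if n_gap > max_gap_fraction * n:
                continue
            if all(w == p or w == "X" for w, p in zip(window, pep_cmp)):
                hits.append(PeptideMapping(
                    structure_id=structure.name,
                    chain=chain,
                    start=info[i][0],
                    end=info[i + n - 1][0],
                    fraction_resolved=1.0 - n_gap / n,
                    match_mode="il_equivalent" if il_equivalent else "exact",
                ))
                chain_hits += 1
        if chain_hits > 1:
            warnings.warn(
                f"peptide {pep} matches {chain_hits} times in chain "
                f"{chain} of {structure.name}; all reported",
                stacklevel=2,
            )
    return hits


# ---------------------------------------------------------------------------
# K_SASA and contacts
# ---------------------------------------------------------------------------

def _subset_sasa(atoms: pd.DataFrame, index, probe_radius: float,
                 n_points: int) -> float:
    """Summed SASA of the atoms at ``index``, occluded by all of ``atoms``."""
    heavy = atoms[atoms["element"].str.upper() != "H"]
    pos = heavy.index.get_indexer(index)
    pos = pos[pos >= 0]
    areas = shrake_rupley(
        heavy[["x", "y", "z"]].to_numpy(), heavy["element"].tolist(),
        probe_radius=probe_radius, n_points=n_points, subset=pos,
    )
    return float(areas[pos].sum())

def k_sasa(
    mapping: PeptideMapping,
    structure: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> float:
    """SASA(peptide | complex) / SASA(peptide | own chain alone).

    The denominator keeps the peptide inside its full parent chain
    (extracted from the complex), so K isolates the burial contributed
    by partner chains. Returns NaN (with a warning) when the peptide
    is already fully buried within its own chain.
    """
    pep_idx = structure.peptide_atoms(mapping.chain, mapping.start,
                                      mapping.end).index
    num = _subset_sasa(structure.atoms, pep_idx, probe_radius, n_points)
    den = _subset_sasa(structure.chain_atoms(mapping.chain), pep_idx,
                       probe_radius, n_points)
    if den <= 0.0:
        warnings.warn(
            "peptide fully buried within its own chain; K_SASA undefined",
            stacklevel=2,
        )
        return float("nan")
    return num / den


def peptide_isolated_sasa(
    mapping: PeptideMapping,
    structure: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> float:
    """SASA of the mapped peptide within its own chain alone, A^2."""
    pep_idx = structure.peptide_atoms(mapping.chain, mapping.start,
                                      mapping.end).index
    return _subset_sasa(structure.chain_atoms(mapping.chain), pep_idx,
                        probe_radius, n_points)


def min_partner_distance(mapping: PeptideMapping,
                         structure: StructureModel) -> float:
    """Minimum heavy-atom distance from the peptide to any other chain."""
    pep = structure.peptide_atoms(mapping.chain, mapping.start, mapping.end)
    partners = structure.atoms[structure.atoms["chain"] != mapping.chain]
    if partners.empty:
        return float("inf")
    tree = cKDTree(partners[["x", "y", "z"]].to_numpy())
    d, _ = tree.query(pep[["x", "y", "z"]].to_numpy())
    return float(np.min(d))


_HB_ELEMENTS = {"N", "O", "S"}
_BOND_CUTOFF = 1.9  # A, heavy-atom covalent bond inference
HB_DISTANCE = 3.5   # A, donor-acceptor heavy-atom cutoff
HB_ANGLE = 120.0    # deg, D-H...A when hydrogens are present
HP_DISTANCE = 5.0   # A, apolar carbon-carbon contact


def _bond_lists(atoms: pd.DataFrame) -> list[list[int]]:
    coords = atoms[["x", "y", "z"]].to_numpy()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(_BOND_CUTOFF)
    bonds: list[list[int]] = [[] for _ in range(len(atoms))]
    for i, j in pairs:
        bonds[i].append(j)
        bonds[j].append(i)
    return bonds


def count_contacts(mapping: PeptideMapping,
                   structure: StructureModel) -> tuple[int, int]:
    """(HB, HP) between the peptide and all non-peptide atoms.

    HB counts N/O/S–N/O/S pairs within 3.5 A (directly bonded pairs
    excluded); when the structure carries hydrogens a D–H···A angle of
    at least 120 deg is additionally required. HP counts pairs of
    apolar carbons (carbon with no bonded N or O) within 5.0 A. Both
    are counted against everything outside the peptide — own-chain
    context included — because partner-only counting is a stricter
    reading the descriptors do not require.
    """
    atoms = structure.atoms.reset_index(drop=True)
    coords = atoms[["x", "y", "z"]].to_numpy()
    elements = atoms["element"].str.upper().to_numpy()
    in_pep = (
        (atoms["chain"] == mapping.chain)
        & (atoms["resseq"] >= mapping.start)
        & (atoms["resseq"] <= mapping.end)
    ).to_numpy()

    bonds = _bond_lists(atoms)
    bonded_elements = [set(elements[j] for j in bonds[i])
                       for i in range(len(atoms))]
    has_h = "H" in set(elements)

    heavy = elements != "H"
    apolar_c = np.array([
        elements[i] == "C" and not ({"N", "O"} & bonded_elements[i])
        for i in range(len(atoms))
    ])
    polar = np.isin(elements, list(_HB_ELEMENTS))

    tree = cKDTree(coords)
    hb = 0
    hp = 0
    pep_heavy = np.where(in_pep & heavy)[0]
    bond_sets = [set(b) for b in bonds]
    for i in pep_heavy:
        neigh = tree.query_ball_point(coords[i], HP_DISTANCE)
        for j in neigh:
            if in_pep[j] or j in bond_sets[i] or not heavy[j]:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if polar[i] and polar[j] and d <= HB_DISTANCE:
                if not has_h or _hb_angle_ok(i, j, coords, elements, bonds):
                    hb += 1
            if apolar_c[i] and apolar_c[j] and d <= HP_DISTANCE:
                hp += 1
    return hb, hp


def _hb_angle_ok(i: int, j: int, coords, elements, bonds) -> bool:
    """D-H...A angle >= HB_ANGLE for any hydrogen on either end."""
    for donor, acceptor in ((i, j), (j, i)):
        hydrogens = [k for k in bonds[donor] if elements[k] == "H"]
        if not hydrogens:
            continue
        for h in hydrogens:
            v1 = coords[donor] - coords[h]
            v2 = coords[acceptor] - coords[h]
            cosang = np.dot(v1, v2) / (
                np.linalg.norm(v1) * np.linalg.norm(v2)
            )
            ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            if ang >= HB_ANGLE:
                return True
    # no hydrogen on either partner: fall back to the distance criterion
    return all(elements[k] != "H" for end in (i, j) for k in bonds[end])


# ---------------------------------------------------------------------------
# Classification and aggregation
# ---------------------------------------------------------------------------

K_IN = 0.9
K_NEAR = 1.1
NEAR_DISTANCE = 8.0  # A
SURFACE_REFERENCE = 100.0  # A^2 of reference exposure per residue


def classify_location(
    k_values,
    min_distance: float,
    peptide_sasa_isolated: float | None = None,
    peptide_length: int | None = None,
    k_in: float = K_IN,
    k_near: float = K_NEAR,
    near_distance: float = NEAR_DISTANCE,
) -> tuple[str, bool | None]:
    """Interface location class and surface flag.

    mean K < ``k_in`` -> "In"; mean K in [k_in, k_near] with the
    peptide within ``near_distance`` of a partner chain -> "Near";
    otherwise "Out". The surface flag is True when the peptide's
    isolated-chain SASA reaches 20% of a reference exposure of
    100 A^2 per residue (None when inputs are not supplied).
    """
    ks = np.asarray(list(np.atleast_1d(k_values)), dtype=float)
    ks = ks[~np.isnan(ks)]
    if ks.size == 0:
        raise ValueError("no finite K_SASA values to classify")
    mean_k = float(ks.mean())
    if mean_k < k_in:
        cls = "In"
    elif mean_k <= k_near and min_distance <= near_distance:
        cls = "Near"
    else:
        cls = "Out"
    surface = None
    if peptide_sasa_isolated is not None and peptide_length is not None:
        surface = peptide_sasa_isolated >= 0.2 * peptide_length * SURFACE_REFERENCE
    return cls, surface


@dataclass
class ComplexDescriptors:
    """Descriptors of one peptide in one complex."""

    structure_id: str
    chain: str
    k_sasa: float
    hb: int
    hp: int
    min_partner_distance: float
    peptide_sasa_isolated: float
    partner_chains: list[str] = field(default_factory=list)


@dataclass
class InterfaceReport:
    """Aggregate over the complexes evaluated for one peptide."""

    peptide: str
    protein_id: str
    n_structures: int
    n_complexes: int
    k_mean: float
    k_sd: float
    hb_mean: float
    hb_sd: float
    hp_mean: float
    hp_sd: float
    location_class: str
    surface_flag: bool | None
    per_complex: list[ComplexDescriptors] = field(default_factory=list)

    @property
    def pdb_counts(self) -> str:
        """'in-complex/screened' counts, Table-style."""
        return f"{self.n_complexes}/{self.n_structures}"


def describe_complex(
    query: PeptideQuery,
    structure: StructureModel,
    mapping: PeptideMapping | None = None,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_SPHERE_POINTS,
) -> ComplexDescriptors | None:
    """All descriptors of one peptide in one complex, or None if unmapped."""
    if mapping is None:
        maps = map_peptide(query, structure)
        if not maps:
            return None
        mapping = maps[0]
    k = k_sasa(mapping, structure, probe_radius, n_points)
    hb, hp = count_contacts(mapping, structure)
    dist = min_partner_distance(mapping, structure)
    iso = peptide_isolated_sasa(mapping, structure, probe_radius, n_points)
    partners = [c for c in structure.chains if c != mapping.chain]
    return ComplexDescriptors(
        structure_id=structure.name, chain=mapping.chain, k_sasa=k,
        hb=hb, hp=hp, min_partner_distance=dist,
        peptide_sasa_isolated=iso, partner_chains=partners,
    )


def aggregate_complexes(
    query: PeptideQuery,
    descriptors: list[ComplexDescriptors],
    n_structures_screened: int | None = None,
) -> InterfaceReport:
    """Mean +/- population sd of K/HB/HP and the aggregate location class."""
    if not descriptors:
        raise ValueError("no per-complex descriptors to aggregate")
    ks = np.array([d.k_sasa for d in descriptors], dtype=float)
    hbs = np.array([d.hb for d in descriptors], dtype=float)
    hps = np.array([d.hp for d in descriptors], dtype=float)
    min_dist = min(d.min_partner_distance for d in descriptors)
    iso = float(np.mean([d.peptide_sasa_isolated for d in descriptors]))
    cls, surface = classify_location(
        ks, min_dist, peptide_sasa_isolated=iso,
        peptide_length=len(query.peptide),
    )
    return InterfaceReport(
        peptide=query.peptide,
        protein_id=query.protein_id,
        n_structures=(n_structures_screened
                      if n_structures_screened is not None
                      else len(descriptors)),
        n_complexes=len(descriptors),
        k_mean=float(np.nanmean(ks)),
        k_sd=float(np.nanstd(ks)),
        hb_mean=float(hbs.mean()),
        hb_sd=float(hbs.std()),
        hp_mean=float(hps.mean()),
        hp_sd=float(hps.std()),
        location_class=cls,
        surface_flag=surface,
        per_complex=descriptors,
    )
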