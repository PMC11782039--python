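"""Synthetic cohorts, PSM tables, and toy complexes.

The generator emulates the statistical shape of a label-free plasma
proteomics study of three groups (controls plus two disease groups of
roughly 24–26 subjects): protein baselines are log-normal with a
dynamic range of about four orders of magnitude, per-sample loading
offsets mimic injection variability, group effects multiply a
protein's abundance in one group, and missingness mixes a random
(MCAR) component with an intensity-dependent left-censoring (MNAR)
component, as expected for low-abundance plasma proteins.

Toy two-chain complexes give the structural stage a controllable
ground truth: chain A is an extended CA-trace carrying a designated
peptide, chain B a partner cage whose radius is calibrated so that a
requested fraction of the peptide's solvent-accessible surface is
occluded in the complex.

Everything is deterministic per seed: identical seeds give
bit-identical tables and structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interface import shrake_rupley
from .io_formats import GroupManifest, IntensityMatrix, PSMTable, StructureModel

__all__ = [
    "CohortDesign",
    "EffectSpec",
    "MissingnessSpec",
    "ToyComplexSpec",
    "MissingnessResult",
    "ToyComplex",
    "generate_cohort",
    "apply_missingness",
    "generate_psm_table",
    "generate_toy_complex",
]


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Study design for the simulator.

    Parameters
    ----------
    group_sizes : dict
        Group label -> number of samples; all counts > 0.
    n_proteins : int
        Number of proteins in the panel.
    base_log_mean, base_log_sd : float
        Mean and sd (log10 units) of protein baseline abundances;
        sd 0.8 spans ~4 orders of magnitude across the panel.
    sample_log_sd : float
        Within-group biological/technical scatter per cell, log10.
        The default 0.12 is calibrated so that 1.5–2-fold group
        differences reach BH-adjusted significance at ~25 samples per
        group, the significance scale the study's DEP table reports.
    loading_log_sd : float
        Sd of the per-sample loading offset (shared across proteins),
        log10; this is what the OLS imputation regresses on. Default 0:
        the emulated quantitation tables are per-injection calibrated
        concentrations, so systematic loading differences are already
        removed upstream. Imputation experiments set it explicitly.
    seed : int
        Bit-reproducibility contract: same seed, same output.
    """

    group_sizes: dict[str, int]
    n_proteins: int = 650
    base_log_mean: float = 6.0
    base_log_sd: float = 0.8
    sample_log_sd: float = 0.12
    loading_log_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("no groups")
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group {g!r} has non-positive size {n}")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")

    @classmethod
    def default_study(cls, seed: int = 0, n_proteins: int = 650
                      ) -> "CohortDesign":
        """Three-arm design shaped like the study cohort."""
        return cls(group_sizes={"CNTR": 24, "KD": 25, "KC": 26},
                   n_proteins=n_proteins, seed=seed)


@dataclass
class EffectSpec:
    """One injected group effect: multiply (|fc| >= 1) or divide."""

    protein_id: str
    group: str
    fold_change: float

    def __post_init__(self) -> None:
        if abs(self.fold_change) < 1:
            raise ValueError(
                f"|fold_change| must be >= 1, got {self.fold_change}"
            )


def protein_id(i: int) -> str:
    return f"P{i + 1:04d}"


def generate_cohort(
    design: CohortDesign,
    effects: list[EffectSpec] | None = None,
) -> tuple[IntensityMatrix, GroupManifest]:
    """Simulate a proteins x samples intensity matrix plus its manifest.

    log10 intensity = protein baseline + sample loading + noise; each
    effect multiplies (positive fc) or divides (negative fc) the target
    group's values for that protein by \\|fc\\|, so the group median moves
    by exactly that factor in expectation.
    """
    effects = effects or []
    rng = np.random.default_rng(design.seed)
    groups = list(design.group_sizes)
    sample_ids = []
    sample_groups = []
    for g in groups:
        for k in range(design.group_sizes[g]):
            sample_ids.append(f"{g}_{k + 1:02d}")
            sample_groups.append(g)
    proteins = [protein_id(i) for i in range(design.n_proteins)]

    for eff in effects:
        if eff.group not in design.group_sizes:
            raise ValueError(f"unknown group label {eff.group!r}")
        if eff.protein_id not in proteins:
            raise ValueError(f"unknown protein id {eff.protein_id!r}")

    base = rng.normal(design.base_log_mean, design.base_log_sd,
                      design.n_proteins)
    loading = rng.normal(0.0, design.loading_log_sd, len(sample_ids))
    noise = rng.normal(0.0, design.sample_log_sd,
                       (design.n_proteins, len(sample_ids)))
    log10x = base[:, None] + loading[None, :] + noise
    values = pd.DataFrame(10.0 ** log10x, index=proteins, columns=sample_ids)

    group_of = pd.Series(sample_groups, index=sample_ids)
    for eff in effects:
        cols = group_of.index[group_of == eff.group]
        factor = abs(eff.fold_change)
        if eff.fold_change >= 0:
            values.loc[eff.protein_id, cols] *= factor
        else:
            values.loc[eff.protein_id, cols] /= factor

    manifest = GroupManifest(group_of.rename("group"))
    return IntensityMatrix(values), manifest


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

@dataclass
class MissingnessSpec:
    """MCAR rate plus a logistic left-censoring (MNAR) component.

    A cell of log10 intensity L goes missing with probability
    ``mcar_rate + sigmoid(-slope * (L - midpoint))`` clipped to
    [0, 1); with ``slope == 0`` the MNAR term is off entirely (the
    sigmoid would otherwise contribute a constant 1/2).
    """

    mcar_rate: float = 0.05
    mnar_logistic_midpoint: float = 4.8
    mnar_logistic_slope: float = 2.0

    def __post_init__(self) -> None:
        if not 0 <= self.mcar_rate < 1:
            raise ValueError("mcar_rate outside [0, 1)")
        if self.mnar_logistic_slope < 0:
            raise ValueError("slope must be >= 0")

    def missing_probability(self, values: np.ndarray) -> np.ndarray:
        p = np.full(np.shape(values), float(self.mcar_rate))
        if self.mnar_logistic_slope > 0:
            z = -self.mnar_logistic_slope * (
                np.log10(values) - self.mnar_logistic_midpoint
            )
            p = p + 1.0 / (1.0 + np.exp(-z))
        return np.clip(p, 0.0, 1.0 - 1e-12)


@dataclass
class MissingnessResult:
    """Masked matrix plus the ground truth for recovery experiments."""

    matrix: IntensityMatrix
    mask: pd.DataFrame           # True where a cell was removed
    truth: IntensityMatrix      # the unmasked original


def apply_missingness(
    matrix: IntensityMatrix,
    spec: MissingnessSpec,
    seed: int,
) -> MissingnessResult:
    """Independently censor cells; the original is kept for recovery tests."""
    if matrix.values.isna().any().any():
        raise ValueError("matrix already has missing cells")
    rng = np.random.default_rng(seed)
    vals = matrix.values.to_numpy()
    p = spec.missing_probability(vals)
    mask = rng.random(vals.shape) < p
    censored = matrix.values.mask(
        pd.DataFrame(mask, index=matrix.values.index,
                     columns=matrix.values.columns)
    )
    return MissingnessResult(
        matrix=IntensityMatrix(censored),
        mask=pd.DataFrame(mask, index=matrix.values.index,
                          columns=matrix.values.columns),
        truth=matrix.copy(),
    )


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

_PHOSPHO_BY_RESIDUE = {"S": "SEP", "T": "TPO", "Y": "PTR"}
_PEPTIDE_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def generate_psm_table(
    matrix: IntensityMatrix,
    phospho_fraction: float = 0.1,
    seed: int = 0,
    min_peptides: int = 2,
    max_peptides: int = 5,
) -> PSMTable:
    """Explode a protein matrix into peptide-level PSM rows.

    Every protein gets at least two distinct peptides (so the
    two-peptide identification rule can pass), each guaranteed to
    contain a phosphorylatable residue. Peptide intensities are fixed
    fractions of the protein intensity, so PSMs sum back to the protein
    value per sample exactly. Each observed PSM is independently the
    phosphorylated form with probability ``phospho_fraction``; the
    modification type (SEP/TPO/PTR) follows the residue at the chosen
    site.
    """
    if not 0 <= phospho_fraction <= 1:
        raise ValueError("phospho_fraction outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for pid in matrix.protein_ids:
        n_pep = int(rng.integers(min_peptides, max_peptides + 1))
        peptides = [_random_peptide(rng) for _ in range(n_pep)]
        while len(set(peptides)) < n_pep:  # vanishingly rare
            peptides = [_random_peptide(rng) for _ in range(n_pep)]
        shares = rng.dirichlet(np.full(n_pep, 5.0))
        gene = "G" + pid[1:]
        prot_values = matrix.values.loc[pid]
        for sid, value in prot_values.items():
            if np.isnan(value):
                continue
            for pep, share in zip(peptides, shares):
                mod_type = "none"
                mod_site: float | int = np.nan
                if rng.random() < phospho_fraction:
                    sites = [k for k, aa in enumerate(pep)
                             if aa in _PHOSPHO_BY_RESIDUE]
                    site = int(rng.choice(sites))
                    mod_type = _PHOSPHO_BY_RESIDUE[pep[site]]
                    mod_site = site + 1
                rows.append((pid, gene, pep, mod_type, mod_site, sid,
                             value * share))
    df = pd.DataFrame(rows, columns=["protein_id", "gene", "peptide",
                                     "mod_type", "mod_site", "sample_id",
                                     "intensity"])
    return PSMTable(df, site_convention="peptide")


def _random_peptide(rng: np.random.Generator, lo: int = 8, hi: int = 15) -> str:
    n = int(rng.integers(lo, hi + 1))
    letters = rng.choice(_PEPTIDE_ALPHABET, n)
    pep = "".join(letters)
    if not set(pep) & set(_PHOSPHO_BY_RESIDUE):
        pos = int(rng.integers(0, n))
        aa = str(rng.choice(list(_PHOSPHO_BY_RESIDUE)))
        pep = pep[:pos] + aa + pep[pos + 1:]
    return pep


# ---------------------------------------------------------------------------
# Toy complexes
# ---------------------------------------------------------------------------

CA_SPACING = 3.8     # A between consecutive CA atoms
_CAGE_SPACING = 1.8  # A between cage atoms (seals against a 1.4 A probe)
_CAGE_R_MIN = 4.0    # A, closest calibratable cage radius
_CAGE_R_FAR = 30.0   # A, beyond any contact with the peptide


@dataclass
class ToyComplexSpec:
    """Recipe for a two-chain complex with controllable peptide burial."""

    peptide_length: int = 10
    burial_fraction: float = 0.5
    partner_offset: float = 0.0  # extra A the cage is pushed outward
    seed: int = 0
    n_flank: int = 4

    def __post_init__(self) -> None:
        if self.peptide_length < 3:
            raise ValueError("peptide_length must be >= 3")
        if not 0 <= self.burial_fraction <= 1:
            raise ValueError("burial_fraction outside [0, 1]")


@dataclass
class ToyComplex:
    structure: StructureModel
    peptide: str
    chain: str
    start: int  # resseq of first peptide residue
    end: int
    achieved_burial: float
    cage_radius: float


# peptide letters avoid A (flanks) and G (cage) so matches are unique
_TOY_LETTERS = np.array(list("CDEFHIKLMNPQRSTVWY"))
_THREE_OF = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


def _chain_a(peptide: str, n_flank: int):
    seq = "A" * n_flank + peptide + "A" * n_flank
    coords = np.array([[i * CA_SPACING, 0.0, 0.0] for i in range(len(seq))])
    return seq, coords


def _cage_coords(x_lo: float, x_hi: float, radius: float) -> np.ndarray:
    """Open tube of cage atoms around the x-axis segment [x_lo, x_hi].

    Point spacing of 1.8 A keeps the wall sealed against a 1.4 A probe;
    at small radii the wall spheres overlap the chain's own spheres, so
    the open ends leak essentially nothing.
    """
    pts = []
    xs = np.arange(x_lo, x_hi + _CAGE_SPACING / 2, _CAGE_SPACING)
    n_ang = max(8, int(np.ceil(2 * np.pi * radius / _CAGE_SPACING)))
    ang = 2 * np.pi * np.arange(n_ang) / n_ang
    for x in xs:
        for a in ang:
            pts.append([x, radius * np.cos(a), radius * np.sin(a)])
    return np.asarray(pts)


def _peptide_burial(chain_coords: np.ndarray, pep_idx: np.ndarray,
                    cage: np.ndarray | None) -> float:
    """1 - SASA(peptide | chain + cage) / SASA(peptide | chain alone)."""
    alone = shrake_rupley(chain_coords, ["C"] * len(chain_coords),
                          subset=pep_idx)
    denom = alone[pep_idx].sum()
    if cage is None or len(cage) == 0:
        return 0.0
    # only cage atoms within reach of the peptide can occlude it
    reach = 2 * (1.87 + 1.4) + 0.1
    pep = chain_coords[pep_idx]
    d = np.linalg.norm(cage[:, None, :] - pep[None, :, :], axis=2)
    near = cage[(d.min(axis=1) < reach)]
    coords = np.vstack([chain_coords, near])
    full = shrake_rupley(coords, ["C"] * len(coords), subset=pep_idx)
    return 1.0 - full[pep_idx].sum() / denom


def generate_toy_complex(spec: ToyComplexSpec) -> ToyComplex:
    """Build a two-chain PDB-writable complex with calibrated burial.

    Chain A is an extended CA trace (alanine flanks around a seeded
    random peptide); chain B is a glycine CA cage (tube plus end caps)
    around the peptide span. The cage radius is found by bisection so
    that the achieved occlusion of the peptide's SASA matches
    ``burial_fraction`` within 0.02; an unreachable request (beyond
    what the tightest cage can occlude) is rejected.
    """
    rng = np.random.default_rng(spec.seed)
    peptide = "".join(rng.choice(_TOY_LETTERS, spec.peptide_length))
    seq_a, coords_a = _chain_a(peptide, spec.n_flank)
    pep_idx = np.arange(spec.n_flank, spec.n_flank + spec.peptide_length)
    x_lo = coords_a[pep_idx[0], 0] - 6.0
    x_hi = coords_a[pep_idx[-1], 0] + 6.0

    target = spec.burial_fraction
    if target == 0.0:
        radius = _CAGE_R_FAR + spec.partner_offset
        achieved = 0.0
    else:
        lo, hi = _CAGE_R_MIN, _CAGE_R_FAR
        max_burial = _peptide_burial(coords_a, pep_idx,
                                     _cage_coords(x_lo, x_hi, lo))
        if target > max_burial + 0.02:
            raise ValueError(
                f"burial_fraction {target} geometrically unreachable "
                f"(max {max_burial:.3f})"
            )
        radius, achieved = lo, max_burial
        for _ in range(24):
            mid = 0.5 * (lo + hi)
            b = _peptide_burial(coords_a, pep_idx,
                                _cage_coords(x_lo, x_hi, mid))
            radius, achieved = mid, b
            if abs(b - target) <= 0.02:
                break
            if b > target:
                lo = mid
            else:
                hi = mid
        radius += spec.partner_offset
        if spec.partner_offset:
            achieved = _peptide_burial(coords_a, pep_idx,
                                       _cage_coords(x_lo, x_hi, radius))

    cage = _cage_coords(x_lo, x_hi, radius)
    structure = _assemble(seq_a, coords_a, cage, spec)
    return ToyComplex(
        structure=structure, peptide=peptide, chain="A",
        start=int(pep_idx[0]) + 1, end=int(pep_idx[-1]) + 1,
        achieved_burial=float(achieved), cage_radius=float(radius),
    )


def _assemble(seq_a: str, coords_a: np.ndarray, cage: np.ndarray,
              spec: ToyComplexSpec) -> StructureModel:
    rows = []
    serial = 1
    chain_residues: dict[str, list[tuple[int, str, str]]] = {"A": [], "B": []}
    for i, (aa, xyz) in enumerate(zip(seq_a, coords_a)):
        rows.append((serial, "CA", "C", "A", i + 1, "", _THREE_OF[aa],
                     xyz[0], xyz[1], xyz[2], 1.0))
        chain_residues["A"].append((i + 1, "", aa))
        serial += 1
    for i, xyz in enumerate(cage):
        rows.append((serial, "CA", "C", "B", i + 1, "", "GLY",
                     round(xyz[0], 3), round(xyz[1], 3), round(xyz[2], 3),
                     1.0))
        chain_residues["B"].append((i + 1, "", "G"))
        serial += 1
    cols = ["serial", "name", "element", "chain", "resseq", "icode",
            "resname", "x", "y", "z", "occupancy"]
    atoms = pd.DataFrame(rows, columns=cols)
    ligands = pd.DataFrame(columns=cols)
    return StructureModel(atoms, ligands, chain_residues,
                          name=f"toy_b{spec.burial_fraction}_s{spec.seed}")
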