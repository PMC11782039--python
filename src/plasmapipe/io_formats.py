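"""Tabular and structural I/O with strict validation.

Containers
----------
:class:`IntensityMatrix`
    Proteins x samples concentration table with explicit missingness
    (NaN) and a boolean imputation mask.
:class:`GroupManifest`
    Sample -> group assignment (CNTR / KD / KC in the study design,
    but any labels are accepted), with optional covariates.
:class:`PSMTable`
    Long-format peptide-spectrum matches with phosphorylation
    annotations (SEP = phospho-Ser, TPO = phospho-Thr, PTR =
    phospho-Tyr).
:class:`StructureModel`
    Polymer atoms of the first model of a PDB/mmCIF file, altloc
    resolved to highest occupancy, plus per-chain one-letter sequences.

All readers reject malformed input with messages that carry locations;
write followed by read is the identity for every emitted format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "GroupManifest",
    "PSMTable",
    "StructureModel",
    "read_quant_table",
    "write_quant_table",
    "read_manifest",
    "write_manifest",
    "read_psm_table",
    "write_psm_table",
    "read_structure",
    "write_structure_pdb",
    "write_structure_cif",
    "apply_two_peptide_rule",
]

MOD_TYPES = ("SEP", "TPO", "PTR")
_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# IntensityMatrix
# ---------------------------------------------------------------------------

@dataclass
class IntensityMatrix:
    """Proteins x samples concentrations; NaN marks a missing cell.

    Parameters
    ----------
    values : pandas.DataFrame
        Index = protein accessions (unique), columns = sample ids
        (unique), float values >= 0 or NaN.
    imputed : pandas.DataFrame, optional
        Boolean mask, same shape; True marks cells filled by the
        imputer. Every imputed cell must be non-missing.
    """

    values: pd.DataFrame
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate protein id {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        arr = v.to_numpy(dtype=float)
        if np.any(np.isinf(arr)):
            raise ValueError("non-finite intensity encountered")
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValueError("negative intensity encountered")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=v.index, columns=v.columns
            )
        else:
            if self.imputed.shape != v.shape:
                raise ValueError("imputed mask shape mismatch")
            self.imputed = self.imputed.astype(bool)
            self.imputed.index = v.index
            self.imputed.columns = v.columns
            bad = self.imputed.to_numpy() & np.isnan(arr)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"cell ({v.index[i]}, {v.columns[j]}) flagged imputed "
                    "but missing"
                )

    # -- convenience ------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def observed_mask(self) -> pd.DataFrame:
        """Cells measured by the instrument (present and not imputed)."""
        return self.values.notna() & ~self.imputed

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.imputed.copy())

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[:, list(sample_ids)].copy(),
            self.imputed.loc[:, list(sample_ids)].copy(),
        )

    def equals(self, other: "IntensityMatrix") -> bool:
        return self.values.equals(other.values) and self.imputed.equals(
            other.imputed
        )


# ---------------------------------------------------------------------------
# GroupManifest
# ---------------------------------------------------------------------------

@dataclass
class GroupManifest:
    """Assignment of every sample to exactly one group."""

    assignments: pd.Series  # index = sample_id, value = group label
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        s = self.assignments
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise ValueError(f"sample {dup!r} assigned more than once")
        if s.isna().any():
            missing = s.index[s.isna()][0]
            raise ValueError(f"sample {missing!r} has no group")
        self.assignments = s.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments.index)

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.assignments:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.assignments):
            raise KeyError(f"group {group!r} absent from manifest")
        return list(self.assignments.index[self.assignments == group])

    def subset(self, sample_ids) -> "GroupManifest":
        cov = None
        if self.covariates is not None:
            cov = self.covariates.loc[list(sample_ids)].copy()
        return GroupManifest(self.assignments.loc[list(sample_ids)].copy(), cov)


# ---------------------------------------------------------------------------
# PSMTable
# ---------------------------------------------------------------------------

_PSM_COLUMNS = ["protein_id", "gene", "peptide", "mod_type", "mod_site",
                "sample_id", "intensity"]


@dataclass
class PSMTable:
    """Long-format PSM rows.

    ``mod_site`` is a 1-based position; the convention (within-protein
    or within-peptide) is declared by ``site_convention``. The
    synthetic generator emits within-peptide coordinates.
    """

    rows: pd.DataFrame
    site_convention: str = "peptide"  # or "protein"

    def __post_init__(self) -> None:
        df = self.rows
        missing_cols = [c for c in _PSM_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"PSM table lacks columns {missing_cols}")
        if (df["intensity"] < 0).any():
            raise ValueError("negative PSM intensity")
        bad_mod = ~df["mod_type"].isin(("none",) + MOD_TYPES)
        if bad_mod.any():
            raise ValueError(
                f"unknown mod_type {df.loc[bad_mod, 'mod_type'].iloc[0]!r}"
            )
        has_site = df["mod_site"].notna()
        if ((df["mod_type"] != "none") != has_site).any():
            raise ValueError("mod_site must be present iff mod_type != none")
        for pep in df["peptide"].unique():
            bad = set(pep) - _AA20
            if bad:
                raise ValueError(
                    f"peptide {pep!r} uses non-standard letters {sorted(bad)}"
                )

    @property
    def protein_ids(self) -> list[str]:
        return list(pd.unique(self.rows["protein_id"]))


def apply_two_peptide_rule(psm: PSMTable) -> set[str]:
    """Identification-quality gate: proteins covered by >= 2 unique peptides.

    Uniqueness is on the bare sequence — the same peptide observed with
    and without a phospho group counts once, because the rule concerns
    sequence coverage, not proteoform diversity.
    """
    counts = psm.rows.groupby("protein_id")["peptide"].nunique()
    return set(counts.index[counts >= 2])


# ---------------------------------------------------------------------------
# Quant table TSV
# ---------------------------------------------------------------------------

def read_quant_table(
    path: str | Path,
    missing_dialect: str = "empty",
    id_column: str = "protein_id",
) -> IntensityMatrix:
    """Read a protein x sample TSV into an :class:`IntensityMatrix`.

    Parameters
    ----------
    missing_dialect : {"empty", "na", "zero"}
        Which cell rendering marks a missing value. PLGS-style exports
        vary, so the dialect is explicit configuration: ``empty`` treats
        empty strings as missing, ``na`` additionally "NA"/"NaN",
        ``zero`` additionally the value 0.
    """
    path = Path(path)
    if missing_dialect not in ("empty", "na", "zero"):
        raise ValueError(f"unknown missing dialect {missing_dialect!r}")
    na_values = [""]
    if missing_dialect in ("na", "zero"):
        na_values += ["NA", "NaN", "nan"]
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=na_values,
                     keep_default_na=False)
    if id_column not in df.columns:
        raise ValueError(f"{path}: no {id_column!r} column in header")
    dup = df[id_column][df[id_column].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate protein row {dup.iloc[0]!r}")
    df = df.set_index(id_column)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )
        df[col] = coerced
    if missing_dialect == "zero":
        df = df.mask(df == 0)
    mask_path = _sidecar_path(path)
    imputed = None
    if mask_path.exists():
        m = pd.read_csv(mask_path, sep="\t", dtype={0: str}).set_index(id_column)
        imputed = m.astype(int).astype(bool)
        imputed = imputed.reindex(index=df.index, columns=df.columns,
                                  fill_value=False)
    return IntensityMatrix(df, imputed)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".imputed.tsv")


def write_quant_table(matrix: IntensityMatrix, path: str | Path) -> None:
    """Write TSV (empty cell = missing) plus an imputation-mask sidecar."""
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t", na_rep="")
    if matrix.imputed.to_numpy().any():
        m = matrix.imputed.astype(int)
        m.index.name = "protein_id"
        m.to_csv(_sidecar_path(path), sep="\t")


def read_manifest(path: str | Path) -> GroupManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: manifest lacks column {col!r}")
    extra = [c for c in df.columns if c not in ("sample_id", "group")]
    cov = df.set_index("sample_id")[extra] if extra else None
    return GroupManifest(df.set_index("sample_id")["group"], cov)


def write_manifest(manifest: GroupManifest, path: str | Path) -> None:
    df = manifest.assignments.rename("group").to_frame()
    df.index.name = "sample_id"
    if manifest.covariates is not None:
        df = df.join(manifest.covariates)
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PSM TSV (wide: one column per sample)
# ---------------------------------------------------------------------------

def write_psm_table(psm: PSMTable, path: str | Path) -> None:
    rows = psm.rows.copy()
    rows["mod_site"] = rows["mod_site"].fillna(-1)  # sentinel for "no site"
    wide = rows.pivot_table(
        index=["protein_id", "gene", "peptide", "mod_type", "mod_site"],
        columns="sample_id", values="intensity", aggfunc="sum",
    )
    wide = wide.reset_index()
    wide["mod_site"] = wide["mod_site"].astype(int).astype("Int64")
    wide.loc[wide["mod_site"] == -1, "mod_site"] = pd.NA
    wide.to_csv(path, sep="\t", index=False, na_rep="")


def read_psm_table(path: str | Path,
                   site_convention: str = "peptide") -> PSMTable:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    key_cols = ["protein_id", "gene", "peptide", "mod_type", "mod_site"]
    for col in key_cols:
        if col not in df.columns:
            raise ValueError(f"{path}: PSM table lacks column {col!r}")
    df["mod_type"] = df["mod_type"].fillna("none")
    sample_cols = [c for c in df.columns if c not in key_cols]
    long = df.melt(id_vars=key_cols, value_vars=sample_cols,
                   var_name="sample_id", value_name="intensity")
    long = long.dropna(subset=["intensity"]).reset_index(drop=True)
    long["mod_site"] = pd.to_numeric(long["mod_site"], errors="coerce")
    return PSMTable(long[_PSM_COLUMNS], site_convention=site_convention)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """Polymer atoms of one model plus per-chain one-letter sequences.

    ``atoms`` columns: serial, name, element, chain, resseq, icode,
    resname, x, y, z, occupancy. ``ligands`` holds non-polymer
    heteroatoms (waters dropped entirely). ``chain_residues`` maps a
    chain id to the ordered list of (resseq, icode, one_letter) of its
    resolved standard residues.
    """

    atoms: pd.DataFrame
    ligands: pd.DataFrame
    chain_residues: dict[str, list[tuple[int, str, str]]] = field(
        default_factory=dict
    )
    name: str = ""

    @property
    def chains(self) -> list[str]:
        return list(self.chain_residues)

    def sequence(self, chain: str) -> str:
        return "".join(r[2] for r in self.chain_residues[chain])

    def chain_atoms(self, chain: str) -> pd.DataFrame:
        return self.atoms[self.atoms["chain"] == chain]

    def peptide_atoms(self, chain: str, start: int, end: int) -> pd.DataFrame:
        """Atoms of chain residues with start <= resseq <= end."""
        a = self.atoms
        sel = (a["chain"] == chain) & (a["resseq"] >= start) & (a["resseq"] <= end)
        return a[sel]


_WATERS = {"HOH", "WAT", "DOD"}


def _one_letter(resname: str) -> str | None:
    info = gemmi.find_tabulated_residue(resname)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code.isalpha() else None


def read_structure(path: str | Path) -> StructureModel:
    """Parse a PDB or mmCIF file (first model only).

    Altlocs are resolved by keeping, per (chain, residue, atom name),
    the conformer with the highest occupancy. Waters are dropped;
    other heteroatoms (ligands, non-standard residues) are kept in a
    separate table and excluded from polymer chains and sequences.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]

    poly_rows: list[tuple] = []
    lig_rows: list[tuple] = []
    chain_residues: dict[str, list[tuple[int, str, str]]] = {}
    for chain in model:
        residues = []
        for res in chain:
            if res.name in _WATERS:
                continue
            one = _one_letter(res.name)
            # resolve altlocs: keep highest-occupancy atom per name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            rows = [
                (atom.serial, atom.name, atom.element.name, chain.name,
                 res.seqid.num, res.seqid.icode.strip(), res.name,
                 atom.pos.x, atom.pos.y, atom.pos.z, atom.occ)
                for atom in best.values()
            ]
            if one is not None:
                poly_rows.extend(rows)
                residues.append((res.seqid.num, res.seqid.icode.strip(), one))
            else:
                lig_rows.extend(rows)
        if residues:
            chain_residues[chain.name] = residues
    if not chain_residues:
        raise ValueError(f"{path}: no polymer chains")
    cols = ["serial", "name", "element", "chain", "resseq", "icode",
            "resname", "x", "y", "z", "occupancy"]
    atoms = pd.DataFrame(poly_rows, columns=cols)
    ligands = pd.DataFrame(lig_rows, columns=cols)
    if not np.isfinite(atoms[["x", "y", "z"]].to_numpy()).all():
        raise ValueError(f"{path}: non-finite coordinates")
    return StructureModel(atoms, ligands, chain_residues, name=path.stem)


_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.name or "model"
    md = gemmi.Model("1")
    for chain_id in model.chains:
        ch = gemmi.Chain(chain_id)
        sub = model.chain_atoms(chain_id)
        for (resseq, icode, resname), grp in sub.groupby(
            ["resseq", "icode", "resname"], sort=True
        ):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(int(resseq), icode or " ")
            for row in grp.itertuples():
                atom = gemmi.Atom()
                atom.name = row.name
                atom.element = gemmi.Element(row.element)
                atom.pos = gemmi.Position(row.x, row.y, row.z)
                atom.occ = float(row.occupancy)
                res.add_atom(atom)
            ch.add_residue(res)
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    return st


def write_structure_pdb(model: StructureModel, path: str | Path) -> None:
    _to_gemmi(model).write_pdb(str(path))


def write_structure_cif(model: StructureModel, path: str | Path) -> None:
    _to_gemmi(model).make_mmcif_document().write_file(str(path))
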