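"""Structure ensembles: RMSF, interaction-strength and GNM networks.

Three residue-level views of a structure are computed here:

* **RMSF** — per-residue root-mean-square fluctuation of the Cα trace
  across ensemble models, RMSF_r = sqrt((1/S) Σ_t |R_r(t) − R_r^ref|²),
  with the per-residue mean coordinate as the default reference.
* **Interaction-strength network** — for residues a, b the percentage
  interaction strength E_ab = 100 · sc_ab / sqrt(sc_a · sc_b), where
  sc_ab counts side-chain heavy-atom pairs within a contact distance and
  sc_a, sc_b are residue-type normalization values; edges are kept when
  E_ab meets the strength threshold E_c (default 4%).
* **GNM correlation network** — the Gaussian network model on Cα contacts:
  the pseudo-inverse of the Kirchhoff matrix gives normalized
  cross-correlations C_ij = Γ⁻¹_ij / sqrt(Γ⁻¹_ii Γ⁻¹_jj); pairs with
  |C_ij| above a threshold (default 0.7) become weighted edges.

A Kyte–Doolittle sliding-window hydropathy profile over a residue stretch
completes the structural characterization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from scipy.spatial.distance import cdist

__all__ = [
    "StructureEnsemble",
    "RMSFProfile",
    "InteractionParams",
    "SIDECHAIN_NORMALIZATION",
    "KYTE_DOOLITTLE",
    "read_structure",
    "rmsf",
    "interaction_network",
    "gnm_correlations",
    "gnm_correlation_network",
    "ensemble_similarity",
    "hydropathy_profile",
]

logger = logging.getLogger(__name__)

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

#: Residue-type side-chain normalization values sc_a for the interaction
#: strength formula — the largest observed side-chain contact capacity per
#: residue type, from the protein structure-graph literature.
SIDECHAIN_NORMALIZATION: Mapping[str, float] = {
    "ALA": 55.76, "ARG": 93.75, "ASN": 73.41, "ASP": 75.15,
    "CYS": 54.95, "GLN": 78.13, "GLU": 78.83, "GLY": 47.31,
    "HIS": 83.74, "ILE": 67.92, "LEU": 72.25, "LYS": 69.61,
    "MET": 69.26, "PHE": 93.31, "PRO": 51.33, "SER": 61.39,
    "THR": 63.71, "TRP": 106.70, "TYR": 100.72, "VAL": 62.37,
}

#: Kyte–Doolittle hydropathy scale (one-letter residue -> index).
KYTE_DOOLITTLE: Mapping[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class EnsembleShapeError(ValueError):
    """Models of one ensemble disagree on residue identity or count."""


@dataclass
class StructureEnsemble:
    """Multi-model Cα + side-chain heavy-atom coordinates of one chain.

    ``ca`` has shape (n_models, n_residues, 3); ``sidechains[m][r]`` is the
    (n_atoms, 3) array of residue r's side-chain heavy atoms in model m
    (glycine is represented by its Cα).
    """

    residue_names: tuple[str, ...]
    residue_ids: tuple[int, ...]
    ca: np.ndarray
    sidechains: list[list[np.ndarray]] = field(repr=False)

    def __post_init__(self) -> None:
        n_models, n_res, _ = self.ca.shape
        if len(self.residue_names) != n_res or len(self.residue_ids) != n_res:
            raise EnsembleShapeError("residue annotation length mismatch")
        if not np.isfinite(self.ca).all():
            raise ValueError("non-finite coordinates")
        if len(self.sidechains) != n_models:
            raise EnsembleShapeError("side-chain model count mismatch")
        for model in self.sidechains:
            if len(model) != n_res:
                raise EnsembleShapeError("side-chain residue count mismatch")

    @property
    def n_models(self) -> int:
        return self.ca.shape[0]

    @property
    def n_residues(self) -> int:
        return self.ca.shape[1]

    @property
    def sequence(self) -> str:
        from Bio.PDB.Polypeptide import protein_letters_3to1

        return "".join(protein_letters_3to1.get(n, "X") for n in self.residue_names)


def read_structure(path: str | Path) -> StructureEnsemble:
    """Parse a (possibly multi-MODEL) PDB file into a structure ensemble.

    Only standard amino-acid residues of the first chain per model are
    kept; hydrogens are ignored and alternate locations resolve to the
    highest-occupancy conformer.  All models must present the same residue
    set.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ens", str(path))
    keys = None
    names: list[str] = []
    ids: list[int] = []
    ca_models: list[np.ndarray] = []
    sc_models: list[list[np.ndarray]] = []
    for model in structure:
        chain = next(iter(model))
        ca_list: list[np.ndarray] = []
        sc_list: list[np.ndarray] = []
        model_keys: list[tuple[str, int]] = []
        for res in chain:
            if not is_aa(res, standard=True):
                continue
            if "CA" not in res:
                raise EnsembleShapeError(
                    f"residue {res.get_resname()}{res.id[1]} lacks a CA atom"
                )
            ca = res["CA"].get_coord().astype(float)
            side = [
                atom.get_coord().astype(float)
                for atom in res.get_atoms()
                if atom.element != "H" and atom.get_name() not in _BACKBONE
            ]
            if not side:  # glycine (or stripped side chain): fall back to CA
                side = [ca]
            ca_list.append(ca)
            sc_list.append(np.array(side))
            model_keys.append((res.get_resname(), res.id[1]))
        if not ca_list:
            raise EnsembleShapeError(f"model {model.id} holds no amino-acid residues")
        if keys is None:
            keys = model_keys
            names = [k[0] for k in keys]
            ids = [k[1] for k in keys]
        elif model_keys != keys:
            raise EnsembleShapeError(
                f"model {model.id} residue set differs from the first model"
            )
        ca_models.append(np.array(ca_list))
        sc_models.append(sc_list)
    return StructureEnsemble(
        residue_names=tuple(names),
        residue_ids=tuple(ids),
        ca=np.stack(ca_models),
        sidechains=sc_models,
    )


@dataclass(frozen=True)
class RMSFProfile:
    """Per-residue Cα fluctuation (Å) plus the reference policy used."""

    residue_ids: tuple[int, ...]
    values: np.ndarray
    reference: str
    superposed: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"residue": self.residue_ids, "rmsf": self.values})


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superposition of `mobile` onto `target` (both (N,3))."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    P, Q = mobile - mc, target - tc
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return P @ R.T + tc


def rmsf(
    ens: StructureEnsemble,
    reference: Literal["mean"] | int = "mean",
    superpose: bool = False,
) -> RMSFProfile:
    """Cα root-mean-square fluctuation per residue over the ensemble.

    The reference is either the per-residue mean coordinate (default) or a
    model index; with ``superpose=True`` every model is least-squares
    superposed onto the reference frame first (for ``mean`` the anchor is
    the first model, after which the mean is recomputed).
    """
    coords = ens.ca.copy()
    if ens.n_models < 2:
        logger.warning("single-model ensemble: RMSF is identically zero")
        return RMSFProfile(ens.residue_ids, np.zeros(ens.n_residues), str(reference), superpose)
    if superpose:
        anchor = coords[0] if reference == "mean" else coords[int(reference)]
        coords = np.stack([_kabsch(m, anchor) for m in coords])
    ref = coords.mean(axis=0) if reference == "mean" else coords[int(reference)]
    sq = ((coords - ref[None]) ** 2).sum(axis=2)  # (S, N)
    values = np.sqrt(sq.mean(axis=0))
    return RMSFProfile(ens.residue_ids, values, str(reference), superpose)


@dataclass(frozen=True)
class InteractionParams:
    """Parameters of the side-chain interaction-strength network.

    ``e_c`` is the percentage strength threshold (default 4%), the contact
    distance is between side-chain heavy atoms, and ``normalization`` maps
    3-letter residue types to their sc_a normalization values.
    """

    e_c: float = 4.0
    contact_distance: float = 4.5
    normalization: Mapping[str, float] = field(
        default_factory=lambda: dict(SIDECHAIN_NORMALIZATION)
    )

    def __post_init__(self) -> None:
        if self.e_c < 0:
            raise ValueError("E_c must be non-negative")
        if any(v <= 0 for v in self.normalization.values()):
            raise ValueError("normalization values must be positive")


def interaction_network(
    ens: StructureEnsemble,
    model: int = 0,
    params: InteractionParams | None = None,
) -> nx.Graph:
    """Side-chain interaction-strength network of one ensemble model.

    Edge (a, b) carries E_ab = 100 · sc_ab / sqrt(sc_a sc_b) whenever this
    percentage reaches ``params.e_c``; nodes are residue sequence numbers.
    """
    params = params or InteractionParams()
    for name in set(ens.residue_names):
        if name not in params.normalization:
            raise KeyError(
                f"residue type {name} missing from the normalization table"
            )
    side = ens.sidechains[model]
    n = ens.n_residues
    g = nx.Graph(provenance="interaction", e_c=params.e_c)
    g.add_nodes_from(ens.residue_ids)
    for a in range(n):
        for b in range(a + 1, n):
            d = cdist(side[a], side[b])
            sc_ab = int((d <= params.contact_distance).sum())
            if sc_ab == 0:
                continue
            norm = np.sqrt(
                params.normalization[ens.residue_names[a]]
                * params.normalization[ens.residue_names[b]]
            )
            strength = 100.0 * sc_ab / norm
            if strength >= params.e_c:
                g.add_edge(ens.residue_ids[a], ens.residue_ids[b], weight=strength)
    return g


def _kirchhoff(coords: np.ndarray, cutoff: float) -> np.ndarray:
    d = cdist(coords, coords)
    contact = (d <= cutoff) & ~np.eye(len(coords), dtype=bool)
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1))
    return gamma


def gnm_correlations(coords: np.ndarray, cutoff: float = 7.3) -> np.ndarray:
    """Normalized GNM cross-correlation matrix of a Cα coordinate set.

    The Kirchhoff matrix of the contact graph at ``cutoff`` is
    pseudo-inverted with its zero mode removed; C_ij = Γ⁻¹_ij /
    sqrt(Γ⁻¹_ii Γ⁻¹_jj), so C_ii = 1 and |C_ij| <= 1.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("GNM needs at least 3 residues")
    gamma = _kirchhoff(coords, cutoff)
    n_comp = _n_components(gamma)
    if n_comp > 1:
        raise ValueError(
            f"contact graph splits into {n_comp} components at cutoff "
            f"{cutoff} Å; increase the cutoff"
        )
    ginv = np.linalg.pinv(gamma, hermitian=True)
    diag = np.sqrt(np.diag(ginv))
    return ginv / np.outer(diag, diag)


def _n_components(gamma: np.ndarray) -> int:
    from scipy.sparse.csgraph import connected_components

    adj = (gamma != 0) & ~np.eye(len(gamma), dtype=bool)
    return int(connected_components(adj, directed=False)[0])


def gnm_correlation_network(
    ens: StructureEnsemble,
    model: int = 0,
    cutoff: float = 7.3,
    corr_threshold: float = 0.7,
) -> nx.Graph:
    """GNM correlation network G_NMA: edges where |C_ij| >= threshold."""
    C = gnm_correlations(ens.ca[model], cutoff=cutoff)
    g = nx.Graph(provenance="nma", cutoff=cutoff, corr_threshold=corr_threshold)
    g.add_nodes_from(ens.residue_ids)
    n = len(C)
    for i in range(n):
        for j in range(i + 1, n):
            c = abs(C[i, j])
            if c >= corr_threshold:
                g.add_edge(ens.residue_ids[i], ens.residue_ids[j], weight=float(c))
    return g


def ensemble_similarity(
    ens: StructureEnsemble, cutoff: float = 7.3
) -> tuple[np.ndarray, int]:
    """Model-by-model similarity of GNM square-fluctuation profiles.

    Each model's profile is the diagonal of its Kirchhoff pseudo-inverse;
    similarity is the Pearson correlation between profiles (NaN where a
    profile is constant).  Returns the similarity matrix and the index of
    the representative model — the one with the highest mean similarity to
    the others (lowest index on ties).
    """
    if ens.n_models < 2:
        raise ValueError("ensemble similarity needs at least 2 models")
    profiles = []
    for m in range(ens.n_models):
        ginv = np.linalg.pinv(_kirchhoff(ens.ca[m], cutoff), hermitian=True)
        profiles.append(np.diag(ginv))
    P = np.array(profiles)
    S = np.ones((ens.n_models, ens.n_models))
    for i in range(ens.n_models):
        for j in range(i + 1, ens.n_models):
            si, sj = P[i].std(), P[j].std()
            if si == 0 or sj == 0:
                S[i, j] = S[j, i] = np.nan
            else:
                S[i, j] = S[j, i] = float(np.corrcoef(P[i], P[j])[0, 1])
    off = S.copy()
    np.fill_diagonal(off, np.nan)
    with np.errstate(invalid="ignore"):
        mean_sim = np.nanmean(off, axis=1)
    representative = int(np.nanargmax(mean_sim))
    return S, representative


def hydropathy_profile(
    seq: str,
    start: int = 40,
    end: int = 95,
    window: int = 9,
    scale: Mapping[str, float] = KYTE_DOOLITTLE,
) -> pd.Series:
    """Sliding-window mean hydropathy over a 1-based inclusive residue range.

    The window is centred on each position and truncated at the sequence
    edges; ``window=1`` returns the raw per-residue scale values.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd count, got {window}")
    n = len(seq)
    if not (1 <= start <= end <= n):
        raise ValueError(f"range {start}-{end} outside sequence of length {n}")
    raw = np.array([scale[a] for a in seq.upper()])
    half = window // 2
    values = {}
    for pos in range(start, end + 1):
        i = pos - 1
        lo, hi = max(0, i - half), min(n, i + half + 1)
        values[pos] = float(raw[lo:hi].mean())
    s = pd.Series(values, name="hydropathy")
    s.index.name = "residue"
    return s
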