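"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the external data the pipeline normally
consumes:

* ``make_msa`` — an aligned family with independently drawn background
  columns, optionally conserved columns, and *planted* covarying column
  pairs whose two-state joint distribution has a tunable coupling; the
  truth record lists the planted pairs and the expected per-column
  entropies.
* ``make_ensemble`` — a noisy multi-model ideal α-helix Cα trace (1.5 Å
  rise, 100° twist per residue) with one radial pseudo side-chain atom
  per residue; per-residue Gaussian noise σ gives a known expected RMSF,
  and an optional outlier model is planted with inflated noise.
* ``make_go_world`` — a rooted ontology DAG with typed is-a/part-of
  edges, leaf-level protein annotations (BP and CC namespaces), a pathway
  membership table with known filter survivors, and a PPI score table
  with a known count above the 0.5 cutoff.

All generators fan a single global seed out into independent per-stage
streams, so outputs are byte-identical across runs and stages do not
perturb each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, AlignedFamily
from .semantics import CONTRIBUTION_FACTORS, PPITable, PathwayCatalog
from .structure import StructureEnsemble

__all__ = [
    "SyntheticSpec",
    "MSATruth",
    "EnsembleTruth",
    "GOWorldTruth",
    "make_msa",
    "make_ensemble",
    "make_go_world",
    "write_pdb",
]

_STAGE_KEYS = {"msa": 101, "ensemble": 202, "go_world": 303}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the three generators, all driven by one seed.

    The defaults are the study conditions the pipeline is exercised
    under: a 500-row, 50-column family with 5 strongly coupled planted
    pairs over a reduced 8-letter alphabet, a 60-residue 10-model helix
    ensemble with 0.5 Å coordinate noise, and a depth-3 ontology world
    with 12 pathways over 20 proteins.
    """

    seed: int = 0
    # --- aligned family
    n_sequences: int = 500
    n_columns: int = 50
    alphabet_size: int = 8
    planted_pairs: tuple[tuple[int, int, float], ...] = (
        (2, 17, 0.9),
        (5, 30, 0.9),
        (9, 44, 0.9),
        (21, 36, 0.9),
        (26, 48, 0.9),
    )
    conserved_columns: tuple[tuple[int, float], ...] = ((0, 1.0), (12, 0.9))
    # --- structure ensemble
    n_residues: int = 60
    n_models: int = 10
    sigma: float = 0.5
    sigma_profile: tuple[float, ...] | None = None
    outlier_model: int | None = None
    outlier_scale: float = 6.0
    # --- ontology world
    dag_depth: int = 3
    dag_branching: int = 3
    part_of_fraction: float = 0.3
    n_proteins: int = 20
    n_pathways: int = 12
    members_per_pathway: int = 4
    n_ppi: int = 25
    query_protein: str = "SNCA"

    def __post_init__(self) -> None:
        planted_cols = {c for s, t, _ in self.planted_pairs for c in (s, t)}
        conserved = {c for c, _ in self.conserved_columns}
        if planted_cols & conserved:
            raise ValueError(
                f"planted pair columns overlap conserved columns: {planted_cols & conserved}"
            )
        for s, t, strength in self.planted_pairs:
            if not (0 <= s < self.n_columns and 0 <= t < self.n_columns and s != t):
                raise ValueError(f"planted pair ({s}, {t}) out of range")
            if not 0.0 <= strength <= 1.0:
                raise ValueError("coupling strength must lie in [0, 1]")
        if self.n_sequences < 2 or self.n_columns < 2:
            raise ValueError("family needs >= 2 sequences and >= 2 columns")
        if not 2 <= self.alphabet_size <= 20:
            raise ValueError("alphabet size must lie in [2, 20]")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([_STAGE_KEYS[stage], self.seed])


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class MSATruth:
    planted_pairs: tuple[tuple[int, int, float], ...]
    conserved_columns: tuple[tuple[int, float], ...]
    expected_column_entropy: tuple[float, ...]


def make_msa(spec: SyntheticSpec) -> tuple[AlignedFamily, MSATruth]:
    """Aligned family with planted covarying pairs and conserved columns.

    Background columns are i.i.d. uniform over the first
    ``alphabet_size`` residues.  A conserved column draws one designated
    residue with its conservation level and is uniform over the rest
    otherwise.  A planted pair (s, t, c) uses two residues per column: a
    hidden fair coin picks column s's state, and column t copies that
    state with probability (1 + c) / 2, giving correlation c between the
    two binary columns.
    """
    rng = spec.rng("msa")
    a = spec.alphabet_size
    letters = np.array(list(AMINO_ACIDS[:a]))
    M, L = spec.n_sequences, spec.n_columns
    cols = rng.integers(0, a, size=(M, L))

    expected = [np.log2(a)] * L
    for col, level in spec.conserved_columns:
        keep = rng.random(M) < level
        cols[keep, col] = 0
        cols[~keep, col] = rng.integers(1, a, size=(~keep).sum())
        p = np.full(a, (1.0 - level) / (a - 1))
        p[0] = level
        expected[col] = _entropy_bits(p)

    for s, t, strength in spec.planted_pairs:
        state = rng.random(M) < 0.5
        copy = rng.random(M) < (1.0 + strength) / 2.0
        other = np.where(copy, state, ~state)
        cols[:, s] = np.where(state, 0, 1)
        cols[:, t] = np.where(other, 2 % a, 3 % a)
        expected[s] = expected[t] = 1.0

    rows = ["".join(letters[r]) for r in cols]
    fam = AlignedFamily.from_sequences(rows, ids=[f"syn{i+1:04d}" for i in range(M)])
    truth = MSATruth(
        planted_pairs=spec.planted_pairs,
        conserved_columns=spec.conserved_columns,
        expected_column_entropy=tuple(expected),
    )
    return fam, truth


@dataclass(frozen=True)
class EnsembleTruth:
    sigma: tuple[float, ...]
    outlier_model: int | None
    expected_rmsf: tuple[float, ...]


_RESIDUE_CYCLE = ("ALA", "LEU", "LYS", "GLU", "VAL", "THR", "SER", "MET")


def make_ensemble(spec: SyntheticSpec) -> tuple[StructureEnsemble, EnsembleTruth]:
    """Noisy multi-model α-helix with pseudo side-chain atoms.

    The expected RMSF about the sample mean at per-coordinate noise σ is
    σ sqrt(3 (S-1)/S) for S models; the truth record stores the σ profile
    and the planted outlier model index (whose noise is scaled by
    ``outlier_scale``).
    """
    rng = spec.rng("ensemble")
    n, S = spec.n_residues, spec.n_models
    sigma = np.asarray(
        spec.sigma_profile
        if spec.sigma_profile is not None
        else np.full(n, spec.sigma),
        dtype=float,
    )
    if sigma.shape != (n,):
        raise ValueError("sigma profile length must match n_residues")
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    ca = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i])
    side = np.column_stack([3.8 * np.cos(theta), 3.8 * np.sin(theta), 1.5 * i])

    ca_models, sc_models = [], []
    for m in range(S):
        scale = spec.outlier_scale if m == spec.outlier_model else 1.0
        noise_ca = rng.normal(0.0, 1.0, size=(n, 3)) * (scale * sigma)[:, None]
        noise_sc = rng.normal(0.0, 1.0, size=(n, 3)) * (scale * sigma)[:, None]
        ca_models.append(ca + noise_ca)
        sc_models.append([(side[r] + noise_sc[r])[None, :] for r in range(n)])
    names = tuple(_RESIDUE_CYCLE[r % len(_RESIDUE_CYCLE)] for r in range(n))
    ens = StructureEnsemble(
        residue_names=names,
        residue_ids=tuple(range(1, n + 1)),
        ca=np.stack(ca_models),
        sidechains=sc_models,
    )
    expected = sigma * np.sqrt(3.0 * (S - 1) / S) if S > 1 else np.zeros(n)
    truth = EnsembleTruth(
        sigma=tuple(sigma),
        outlier_model=spec.outlier_model,
        expected_rmsf=tuple(expected),
    )
    return ens, truth


def write_pdb(ens: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB file (Cα + side-chain atoms)."""
    with open(path, "w") as fh:
        for m in range(ens.n_models):
            fh.write(f"MODEL     {m + 1:>4d}\n")
            serial = 1
            for r in range(ens.n_residues):
                name = ens.residue_names[r]
                rid = ens.residue_ids[r]
                x, y, z = ens.ca[m, r]
                fh.write(
                    f"ATOM  {serial:>5d}  CA  {name:<3s} A{rid:>4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
                serial += 1
                for k, atom in enumerate(ens.sidechains[m][r]):
                    if np.allclose(atom, ens.ca[m, r]):
                        continue  # glycine-style CA stand-in: already written
                    x, y, z = atom
                    fh.write(
                        f"ATOM  {serial:>5d}  CB  {name:<3s} A{rid:>4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                    )
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


@dataclass(frozen=True)
class GOWorldTruth:
    sibling_terms: tuple[str, str]
    expected_sibling_ss: float
    expected_surviving_pathways: tuple[str, ...]
    n_ppi_above_cutoff: int


def make_go_world(
    spec: SyntheticSpec,
) -> tuple[nx.DiGraph, pd.DataFrame, PathwayCatalog, PPITable, GOWorldTruth]:
    """Ontology DAG + annotations + pathway catalog + PPI table, with truth.

    Two namespaces (BP, CC) hang under separate roots.  The first two BP
    children of the root are both attached by is-a edges, so their Wang
    similarity has the closed form (0.8 + 0.8) / (1.8 + 1.8) = 4/9.  The
    truth record also lists the pathways that survive filtering on the
    query protein with >= 2 members, and the count of PPI scores >= 0.5.
    """
    rng = spec.rng("go_world")
    go = nx.DiGraph()
    leaves: dict[str, list[str]] = {}
    for ns in ("BP", "CC"):
        root = f"GO:{ns}:ROOT"
        level = [root]
        counter = 0
        for depth in range(1, spec.dag_depth + 1):
            nxt: list[str] = []
            for parent in level:
                for _ in range(spec.dag_branching):
                    counter += 1
                    child = f"GO:{ns}:{counter:04d}"
                    if ns == "BP" and depth == 1 and counter <= 2:
                        rel = "is_a"  # pin the closed-form sibling pair
                    else:
                        rel = "part_of" if rng.random() < spec.part_of_fraction else "is_a"
                    go.add_edge(child, parent, relation=rel, c_e=CONTRIBUTION_FACTORS[rel])
                    # occasional second parent keeps the graph a true DAG
                    if depth > 1 and rng.random() < 0.2:
                        alt = level[int(rng.integers(0, len(level)))]
                        if alt != parent:
                            rel2 = (
                                "part_of"
                                if rng.random() < spec.part_of_fraction
                                else "is_a"
                            )
                            go.add_edge(
                                child, alt, relation=rel2, c_e=CONTRIBUTION_FACTORS[rel2]
                            )
                    nxt.append(child)
            level = nxt
        leaves[ns] = level

    proteins = [spec.query_protein] + [f"PROT{i:03d}" for i in range(1, spec.n_proteins)]
    ann_rows = []
    for prot in proteins:
        for ns in ("BP", "CC"):
            k = int(rng.integers(2, 5))
            terms = rng.choice(leaves[ns], size=min(k, len(leaves[ns])), replace=False)
            for t in terms:
                ann_rows.append({"protein": prot, "term": str(t), "ontology": ns})
    annotations = pd.DataFrame(ann_rows)

    members: dict[str, frozenset] = {}
    survivors = []
    for p in range(spec.n_pathways):
        pid = f"PW{p + 1:03d}"
        pool = rng.choice(proteins[1:], size=spec.members_per_pathway, replace=False)
        mem = set(str(x) for x in pool)
        if p % 2 == 0:  # every other pathway contains the query protein
            mem.pop()
            mem.add(spec.query_protein)
        members[pid] = frozenset(mem)
        if spec.query_protein in mem and len(mem) >= 2:
            survivors.append(pid)
    catalog = PathwayCatalog(members=members)

    scores = np.round(rng.uniform(0.0, 1.0, size=spec.n_ppi), 3)
    ppi = PPITable(
        query=spec.query_protein,
        table=pd.DataFrame(
            {"partner": [f"PROT{i:03d}" for i in range(1, spec.n_ppi + 1)], "score": scores}
        ),
    )
    truth = GOWorldTruth(
        sibling_terms=("GO:BP:0001", "GO:BP:0002"),
        expected_sibling_ss=(0.8 + 0.8) / (1.8 + 1.8),
        expected_surviving_pathways=tuple(survivors),
        n_ppi_above_cutoff=int((scores >= 0.5).sum()),
    )
    return go, annotations, catalog, ppi, truth
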