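"""Synthetic ortholog families with planted phospho-acceptor gains.

The generator is the test harness for every pipeline stage: it evolves
protein columns down a dated species tree, plants acceptor gains on chosen
branches of the root-to-focal path with known origin residues and age
groups, emits annotation flags whose rates depend on the planted age (the
structure the cohort analyses look for), and draws correlated tissue-level
quantification.  Every planted site keeps a truth record so recovery can be
scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    AMINO_ACIDS,
    DEFAULT_FOCAL_SPECIES,
    DEFAULT_TREE_NEWICK,
    DatedTree,
    InputError,
    OrthologAlignment,
    TreeNode,
    write_alignment_fasta,
    write_quant_tsv,
    write_sites_tsv,
)

N_TISSUES = 9


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


def _default_origin_weights_phospho() -> dict[str, dict[str, float]]:
    # Multipliers over a uniform background of candidate origin residues.
    # Median sites are more Asp/Glu-born than young ones (phosphomimetic
    # ancestry fades in recent gains); Lys is mildly enriched in both.
    return {
        "old": {},
        "median": {"D": 4.0, "E": 4.0, "K": 2.0},
        "young": {"D": 2.0, "E": 2.0, "K": 2.0},
    }


def _default_origin_weights_control() -> dict[str, dict[str, float]]:
    return {"old": {}, "median": {}, "young": {}}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-data generator.

    Probabilities are per site and per branch (not per MY); ages come from
    the embedded Newick tree and must satisfy the dated-tree invariants.
    """

    tree_newick: str = DEFAULT_TREE_NEWICK
    focal_species: str = DEFAULT_FOCAL_SPECIES

    # families / sequence evolution
    n_families: int = 50
    background_columns: int = 40
    substitution_prob: float = 0.05
    prob_missing_species: float = 0.0
    module_mixture: dict[str, float] = field(
        default_factory=lambda: {"BFM": 0.5, "VFM": 0.5}
    )
    #: VFM proteins evolve slower: their substitution probability is scaled.
    module_rate_multiplier: dict[str, float] = field(
        default_factory=lambda: {"BFM": 1.0, "VFM": 0.5}
    )

    # planted sites
    n_phospho_sites: int = 1000
    n_control_sites: int = 1500
    group_mixture: dict[str, float] = field(
        default_factory=lambda: {"old": 1 / 3, "median": 1 / 3, "young": 1 / 3}
    )
    control_group_mixture: dict[str, float] = field(
        default_factory=lambda: {"old": 0.0, "median": 0.5, "young": 0.5}
    )
    residue_probs: dict[str, float] = field(
        default_factory=lambda: {"S": 0.75, "T": 0.20, "Y": 0.05}
    )
    origin_weights_phospho: dict[str, dict[str, float]] = field(
        default_factory=_default_origin_weights_phospho
    )
    origin_weights_control: dict[str, dict[str, float]] = field(
        default_factory=_default_origin_weights_control
    )
    conservation_p: float = 0.9
    harvest_natural_sites: bool = False

    # age thresholds (must match the analysis configuration)
    old_min: float = 435.0
    young_max: float = 96.0

    # structure / annotation
    disordered_frac: float = 0.75
    functional_p: dict[str, float] = field(
        default_factory=lambda: {"old": 0.30, "median": 0.15, "young": 0.05}
    )
    polymorphic_p: dict[str, float] = field(
        default_factory=lambda: {"old": 0.05, "median": 0.10, "young": 0.20}
    )
    control_ptm_db_p: float = 0.08
    kinase_score_scale: float = 1.0

    # tissue quantification
    level_mu: dict[str, float] = field(
        default_factory=lambda: {"old": 1.0, "median": 0.65, "young": 0.3}
    )
    breadth_alpha: dict[str, float] = field(
        default_factory=lambda: {"old": 0.8, "median": 0.4, "young": 0.0}
    )
    #: latent severity couplings: breadth logit slope and log-level slope
    coupling_beta: float = 1.0
    coupling_gamma: float = 0.7
    level_sigma: float = 0.6
    #: pooled Pearson target for max level vs breadth; > 0.95 is infeasible
    level_breadth_target_r: float = 0.46
    protein_breadth_alpha: float = 1.0
    protein_breadth_coupling: float = 0.3

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        errors: list[str] = []

        def check_prob(value: float, key: str) -> None:
            if not 0.0 <= value <= 1.0:
                errors.append(f"{key}: {value} outside [0, 1]")

        check_prob(self.substitution_prob, "substitution_prob")
        check_prob(self.prob_missing_species, "prob_missing_species")
        check_prob(self.conservation_p, "conservation_p")
        check_prob(self.disordered_frac, "disordered_frac")
        check_prob(self.control_ptm_db_p, "control_ptm_db_p")
        for name, mixture in [
            ("group_mixture", self.group_mixture),
            ("control_group_mixture", self.control_group_mixture),
            ("module_mixture", self.module_mixture),
            ("residue_probs", self.residue_probs),
        ]:
            for key, val in mixture.items():
                check_prob(val, f"{name}.{key}")
            if abs(sum(mixture.values()) - 1.0) > 1e-9:
                errors.append(f"{name}: probabilities must sum to 1")
        for name, table in [
            ("functional_p", self.functional_p),
            ("polymorphic_p", self.polymorphic_p),
        ]:
            for key, val in table.items():
                check_prob(val, f"{name}.{key}")
        if not self.old_min > self.young_max > 0:
            errors.append(
                f"old_min ({self.old_min}) must exceed young_max "
                f"({self.young_max}) which must be positive"
            )
        if self.n_families < 1:
            errors.append("n_families: must be >= 1")
        if self.n_phospho_sites < 0 or self.n_control_sites < 0:
            errors.append("site counts must be non-negative")
        if self.level_breadth_target_r > 0.95:
            errors.append(
                f"level_breadth_target_r: {self.level_breadth_target_r} > 0.95 "
                "is infeasible for a 0-9 breadth"
            )
        if self.kinase_score_scale <= 0:
            errors.append("kinase_score_scale: must be positive")
        try:
            DatedTree.from_newick(self.tree_newick, self.focal_species)
        except (ValueError, KeyError) as exc:
            errors.append(f"tree_newick: {exc}")
        return errors

    def tree(self) -> DatedTree:
        return DatedTree.from_newick(self.tree_newick, self.focal_species)

    @classmethod
    def from_dict(cls, data: Mapping) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown generator config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class SimulatedDataset:
    """Everything one generator run produced, truth included."""

    tree: DatedTree
    alignments: dict[str, OrthologAlignment]
    sites: pd.DataFrame
    truth: pd.DataFrame
    quant: pd.DataFrame
    ancestral: dict[str, dict[str, str]] = field(repr=False, default_factory=dict)


# ---------------------------------------------------------------------------
# sequence evolution with planted gains
# ---------------------------------------------------------------------------


@dataclass
class _PlantedSpec:
    site_index: int
    is_phospho: bool
    residue: str
    group: str
    gain_node: str  # name of the node where the acceptor first appears
    gain_age: float
    gain_parent_age: float  # nan at the root
    origin: str | None  # None when gained at the root
    conserve: bool
    column: int = -1


def _path_gain_candidates(
    tree: DatedTree, old_min: float, young_max: float
) -> dict[str, list[TreeNode]]:
    path = tree.path_to_leaf(tree.focal_species)
    cands: dict[str, list[TreeNode]] = {"old": [path[0]], "median": [], "young": []}
    for node in path[1:]:
        if node.age >= old_min:
            cands["old"].append(node)
        elif node.age >= young_max:
            cands["median"].append(node)
        else:
            cands["young"].append(node)
    for group, nodes in cands.items():
        if not nodes:
            raise ConfigError(
                f"tree has no root-to-focal node usable for the {group} group"
            )
    return cands


def _draw_origin(
    rng: np.random.Generator, residue: str, multipliers: Mapping[str, float]
) -> str:
    candidates = [aa for aa in AMINO_ACIDS if aa != residue]
    weights = np.array([multipliers.get(aa, 1.0) for aa in candidates], float)
    weights /= weights.sum()
    return candidates[rng.choice(len(candidates), p=weights)]


def _subtree_names(node: TreeNode) -> set[str]:
    out = set()
    stack = [node]
    while stack:
        n = stack.pop()
        out.add(n.name)
        stack.extend(n.children)
    return out


def simulate_family(
    config: GeneratorConfig,
    tree: DatedTree,
    family_id: str,
    planted: list[_PlantedSpec],
    substitution_prob: float,
    rng: np.random.Generator,
    species: list[str] | None = None,
) -> tuple[OrthologAlignment, dict[str, str]]:
    """Evolve one family down the tree with its planted columns forced.

    The root sequence is drawn uniformly over the 20 residues; each branch
    substitutes every site independently with ``substitution_prob`` to a
    uniformly chosen other residue.  Planted columns override this: nodes on
    the root-to-focal path carry the origin residue above the gain node and
    the acceptor from the gain node down, and (when the spec's ``conserve``
    is set) every descendant of the gain node is forced to the acceptor.

    Returns the alignment (restricted to ``species`` when given) and the
    true sequences of *all* tree nodes, internal nodes included.
    """
    L = config.background_columns + len(planted)
    for i, spec in enumerate(planted):
        spec.column = config.background_columns + i

    path = tree.path_to_leaf(tree.focal_species)
    path_names = [n.name for n in path]
    name_to_node = {n.name: n for n in tree.preorder()}
    for spec in planted:
        if spec.gain_node not in path_names:
            raise ConfigError(
                f"planted gain node {spec.gain_node!r} is not on the "
                "root-to-focal path"
            )

    # per planted column: forced state lookup
    forced: dict[int, dict[str, str]] = {}
    for spec in planted:
        rules: dict[str, str] = {}
        gain_idx = path_names.index(spec.gain_node)
        for j, name in enumerate(path_names):
            rules[name] = spec.residue if j >= gain_idx else spec.origin
        if spec.conserve:
            for name in _subtree_names(name_to_node[spec.gain_node]):
                rules[name] = spec.residue
        forced[spec.column] = rules

    aa_array = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    root_seq = aa_array[rng.integers(0, 20, size=L)].copy()
    for spec in planted:
        root_state = forced[spec.column].get(tree.root.name)
        root_seq[spec.column] = (
            root_state if root_state is not None else root_seq[spec.column]
        )

    sequences: dict[str, np.ndarray] = {tree.root.name: root_seq}
    for node in tree.preorder():
        if node.name not in sequences:  # pragma: no cover - preorder guarantees
            raise AssertionError("parent sequence missing")
        parent_seq = sequences[node.name]
        for child in node.children:
            seq = parent_seq.copy()
            mutate = rng.random(L) < substitution_prob
            if mutate.any():
                # uniform over the 19 other residues
                shifts = rng.integers(1, 20, size=int(mutate.sum()))
                idx = np.array(
                    [aa_index.get(c, rng.integers(0, 20)) for c in seq[mutate]]
                )
                seq[mutate] = aa_array[(idx + shifts) % 20]
            for col, rules in forced.items():
                state = rules.get(child.name)
                if state is not None:
                    seq[col] = state
            sequences[child.name] = seq

    true_seqs = {name: "".join(seq) for name, seq in sequences.items()}
    leaf_names = species if species is not None else tree.leaf_names
    alignment = OrthologAlignment(
        family_id=family_id,
        sequences={name: true_seqs[name] for name in leaf_names},
        focal_species=tree.focal_species,
    )
    return alignment, true_seqs


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def _draw_mixture(
    rng: np.random.Generator, mixture: Mapping[str, float], n: int
) -> list[str]:
    keys = list(mixture)
    probs = np.array([mixture[k] for k in keys], float)
    probs /= probs.sum()
    return [keys[i] for i in rng.choice(len(keys), size=n, p=probs)]


def generate_dataset(config: GeneratorConfig, seed: int) -> SimulatedDataset:
    """Run the full generator: alignments, site table, truth and quant.

    All randomness flows from ``seed`` through a single
    :class:`numpy.random.Generator`; a fixed seed reproduces the dataset
    bit-identically.
    """
    errors = config.validate()
    if errors:
        raise ConfigError("; ".join(errors))
    rng = np.random.default_rng(seed)
    tree = config.tree()
    candidates = _path_gain_candidates(tree, config.old_min, config.young_max)

    # plan planted sites
    specs: list[_PlantedSpec] = []
    for is_phospho, n_sites, mixture, origin_weights in [
        (True, config.n_phospho_sites, config.group_mixture,
         config.origin_weights_phospho),
        (False, config.n_control_sites, config.control_group_mixture,
         config.origin_weights_control),
    ]:
        groups = _draw_mixture(rng, mixture, n_sites)
        residues = _draw_mixture(rng, config.residue_probs, n_sites)
        for group, residue in zip(groups, residues):
            nodes = candidates[group]
            node = nodes[rng.integers(0, len(nodes))]
            if node.parent is None:
                origin = None
                parent_age = float("nan")
            else:
                origin = _draw_origin(rng, residue, origin_weights.get(group, {}))
                parent_age = node.parent.age
            conserve = (
                True if group == "old" else bool(rng.random() < config.conservation_p)
            )
            specs.append(
                _PlantedSpec(
                    site_index=len(specs),
                    is_phospho=is_phospho,
                    residue=residue,
                    group=group,
                    gain_node=node.name,
                    gain_age=node.age,
                    gain_parent_age=parent_age,
                    origin=origin,
                    conserve=conserve,
                )
            )

    # assign sites to families round-robin, then simulate each family
    modules = _draw_mixture(rng, config.module_mixture, config.n_families)
    per_family: list[list[_PlantedSpec]] = [[] for _ in range(config.n_families)]
    for i, spec in enumerate(specs):
        per_family[i % config.n_families].append(spec)

    alignments: dict[str, OrthologAlignment] = {}
    ancestral: dict[str, dict[str, str]] = {}
    site_rows: list[dict] = []
    truth_rows: list[dict] = []
    non_focal = [sp for sp in tree.leaf_names if sp != tree.focal_species]

    for fam_idx in range(config.n_families):
        family_id = f"fam{fam_idx:04d}"
        module = modules[fam_idx]
        p_sub = config.substitution_prob * config.module_rate_multiplier[module]
        species = [tree.focal_species] + [
            sp
            for sp in non_focal
            if rng.random() >= config.prob_missing_species
        ]
        aln, true_seqs = simulate_family(
            config, tree, family_id, per_family[fam_idx], p_sub, rng, species
        )
        alignments[family_id] = aln
        ancestral[family_id] = true_seqs

        for spec in per_family[fam_idx]:
            position = spec.column + 1  # no indels: column == position - 1
            disordered = rng.random() < config.disordered_frac
            disorder = (
                rng.uniform(0.51, 1.0) if disordered else rng.uniform(0.0, 0.5)
            )
            site_rows.append(
                {
                    "family": family_id,
                    "position": position,
                    "residue": spec.residue,
                    "disorder": disorder,
                    "is_phospho": spec.is_phospho,
                    "functional": False,
                    "polymorphic": False,
                    "known_ptm_db": False,
                    "kinase_score": 0.0,
                    "module": module,
                }
            )
            truth_rows.append(
                {
                    "family": family_id,
                    "position": position,
                    "residue": spec.residue,
                    "is_phospho": spec.is_phospho,
                    "gain_node": spec.gain_node,
                    "gain_age": spec.gain_age,
                    "gain_parent_age": spec.gain_parent_age,
                    "origin": spec.origin if spec.origin is not None else "unknown",
                    "group": spec.group,
                    "conserve": spec.conserve,
                    "module": module,
                }
            )

        if config.harvest_natural_sites:
            focal_seq = aln.focal_sequence
            planted_cols = {s.column for s in per_family[fam_idx]}
            for col, char in enumerate(focal_seq):
                if char in "STY" and col not in planted_cols:
                    disordered = rng.random() < config.disordered_frac
                    site_rows.append(
                        {
                            "family": family_id,
                            "position": col + 1,
                            "residue": char,
                            "disorder": rng.uniform(0.51, 1.0)
                            if disordered
                            else rng.uniform(0.0, 0.5),
                            "is_phospho": False,
                            "functional": False,
                            "polymorphic": False,
                            "known_ptm_db": False,
                            "kinase_score": 0.0,
                            "module": module,
                        }
                    )

    sites = pd.DataFrame(site_rows)
    truth = pd.DataFrame(truth_rows)
    sites = generate_annotations(sites, truth, config, rng)
    quant = generate_quant(truth, config, rng)
    return SimulatedDataset(
        tree=tree,
        alignments=alignments,
        sites=sites,
        truth=truth,
        quant=quant,
        ancestral=ancestral,
    )


def generate_annotations(
    sites: pd.DataFrame,
    truth: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw annotation flags with age-dependent rates.

    Functional flags are Bernoulli with probability increasing in planted
    age; polymorphism decreases with age; control sites get PTM-database
    flags and exponential kinase scores at configured rates (the raw
    material for the control-pool filters).
    """
    sites = sites.copy()
    key = ["family", "position"]
    groups = sites.merge(truth[key + ["group"]], on=key, how="left")["group"]

    is_phospho = sites["is_phospho"].to_numpy(bool)
    n = len(sites)
    func_p = groups.map(config.functional_p).fillna(0.0).to_numpy(float)
    poly_p = groups.map(config.polymorphic_p).fillna(0.0).to_numpy(float)
    sites["functional"] = (rng.random(n) < func_p) & is_phospho
    sites["polymorphic"] = (rng.random(n) < poly_p) & is_phospho
    sites["known_ptm_db"] = (rng.random(n) < config.control_ptm_db_p) & ~is_phospho
    scores = rng.exponential(config.kinase_score_scale, size=n)
    sites["kinase_score"] = np.where(is_phospho, 0.0, scores)
    return sites


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_quant(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the nine-tissue quantification table for phospho sites.

    A per-site latent severity ``z`` drives both the breadth (binomial over
    9 tissues with a logit-linear success probability) and the log maximum
    level, producing the configured pooled level-breadth correlation; group
    offsets plant the old > young level and breadth effects.  Protein
    abundance is drawn independently of age group.
    """
    phospho = truth[truth["is_phospho"]].reset_index(drop=True)
    n = len(phospho)
    z = rng.normal(size=n)
    alpha = phospho["group"].map(config.breadth_alpha).to_numpy(float)
    mu = phospho["group"].map(config.level_mu).to_numpy(float)

    breadth_p = _sigmoid(alpha + config.coupling_beta * z)
    breadth = rng.binomial(N_TISSUES, breadth_p)
    max_level = np.exp(
        mu + config.coupling_gamma * z + config.level_sigma * rng.normal(size=n)
    )
    max_level = np.where(breadth > 0, max_level, 0.0)

    tissue_levels = np.zeros((n, N_TISSUES))
    for i in range(n):
        b = int(breadth[i])
        if b == 0:
            continue
        tissues = rng.choice(N_TISSUES, size=b, replace=False)
        levels = np.empty(b)
        levels[0] = max_level[i]
        if b > 1:
            levels[1:] = rng.uniform(0.0, max_level[i], size=b - 1)
        tissue_levels[i, tissues] = levels

    protein_abundance = np.exp(rng.normal(size=n))
    protein_breadth = rng.binomial(
        N_TISSUES,
        _sigmoid(config.protein_breadth_alpha + config.protein_breadth_coupling * z),
    )

    out = pd.DataFrame(
        {
            "family": phospho["family"],
            "position": phospho["position"],
        }
    )
    for t in range(N_TISSUES):
        out[f"tissue_{t + 1}"] = tissue_levels[:, t]
    out["protein_abundance"] = protein_abundance
    out["protein_breadth"] = protein_breadth
    return out


# ---------------------------------------------------------------------------
# statistic-level origin sampler (for calibration/power studies)
# ---------------------------------------------------------------------------


def sample_origin_labels(
    n_phospho: int,
    n_control: int,
    rng: np.random.Generator,
    phospho_multipliers: Mapping[str, float] | None = None,
    control_multipliers: Mapping[str, float] | None = None,
    disordered_frac: float = 0.75,
    residue_probs: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw origin/structure labels directly, skipping sequence evolution.

    Used for replicated calibration and power studies of the bootstrap
    enrichment where only the joint (origin, structure, residue)
    distribution matters; the full generator plants the same distributions
    through actual sequence gains.
    """
    residue_probs = dict(residue_probs or {"S": 0.75, "T": 0.20, "Y": 0.05})

    def draw(n: int, multipliers: Mapping[str, float]) -> pd.DataFrame:
        residues = _draw_mixture(rng, residue_probs, n)
        origins = [
            _draw_origin(rng, res, multipliers or {}) for res in residues
        ]
        structure = np.where(
            rng.random(n) < disordered_frac, "disordered", "ordered"
        )
        return pd.DataFrame(
            {
                "family": "pool",
                "position": np.arange(1, n + 1),
                "residue": residues,
                "origin": origins,
                "structure": structure,
            }
        )

    phospho = draw(n_phospho, phospho_multipliers or {})
    phospho["is_phospho"] = True
    control = draw(n_control, control_multipliers or {})
    control["is_phospho"] = False
    return phospho, control


# ---------------------------------------------------------------------------
# writing the exact formats the readers consume
# ---------------------------------------------------------------------------


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write tree, alignments, site/quant/truth tables under ``outdir``.

    Returns a manifest-friendly mapping of artifact name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    tree_path = outdir / "tree.nwk"
    dataset.tree.write(tree_path)
    paths["tree"] = str(tree_path)

    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for family_id in sorted(dataset.alignments):
        write_alignment_fasta(
            dataset.alignments[family_id], aln_dir / f"{family_id}.fasta"
        )
    paths["alignments"] = str(aln_dir)

    sites_path = outdir / "sites.tsv"
    write_sites_tsv(dataset.sites, sites_path)
    paths["sites"] = str(sites_path)

    truth_path = outdir / "truth.tsv"
    dataset.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = str(truth_path)

    quant_path = outdir / "quant.tsv"
    write_quant_tsv(dataset.quant, quant_path)
    paths["quant"] = str(quant_path)
    return paths
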