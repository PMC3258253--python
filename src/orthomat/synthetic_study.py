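"""Ground-truthed synthetic transcriptome study generator.

Emulates the data structure of a charophyte phylogenomic study: six
reference taxa with complete proteomes (four land plants, two chlorophyte
outgroups) and eight transcriptome taxa with incomplete unigene sets.
Genes evolve on a known 14-taxon species tree (Zygnematales sister to
land plants) with controlled gene duplication and loss, per-taxon
occupancy, amino-acid composition bias, and a configurable minority of
genes evolved on a conflicting topology (Charales sister to land plants).
Every run is fully reproducible from one integer seed and returns a
:class:`TruthBundle` with the complete ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import (
    AMINO_ACIDS,
    MultipleAlignment,
    SeqRecord,
    log_stage,
    make_id,
    read_newick,
    write_fasta,
)
from .ml_engine.models import SubstitutionModel, lg_model
from .tree import Node, PhyloTree

REFERENCE_TAXA = [
    "Arabidopsis",
    "Populus",
    "Oryza",
    "Physcomitrella",
    "Ostreococcus",
    "Chlamydomonas",
]
TRANSCRIPTOME_TAXA = [
    "Chlorokybus",
    "Chaetosphaeridium",
    "Coleochaete",
    "Klebsormidium",
    "Mesostigma",
    "Nitella",
    "Penium",
    "Spirogyra",
]
LAND_PLANTS = ["Arabidopsis", "Populus", "Oryza", "Physcomitrella"]
CHLOROPHYTES = ["Ostreococcus", "Chlamydomonas"]

# 14-taxon species tree: Zygnematales (Penium, Spirogyra) sister to land
# plants, Coleochaetales next, then Charales (Nitella), Klebsormidium and
# the Chlorokybus+Mesostigma lineage; chlorophytes are the outgroup.
DEFAULT_SPECIES_TREE = (
    "((Chlamydomonas:0.45,Ostreococcus:0.50):0.25,"
    "((Mesostigma:0.35,Chlorokybus:0.30):0.08,"
    "(Klebsormidium:0.35,"
    "(Nitella:0.30,"
    "((Coleochaete:0.25,Chaetosphaeridium:0.30):0.08,"
    "((Penium:0.30,Spirogyra:0.30):0.10,"
    "(Physcomitrella:0.25,(Oryza:0.20,(Arabidopsis:0.15,Populus:0.15):0.05):0.05):0.12"
    "):0.06):0.05):0.06):0.07):0.15);"
)

# conflicting history used for incongruent genes: Charales sister to LP
ALTERNATIVE_TOPOLOGY = (
    "((Chlamydomonas:0.45,Ostreococcus:0.50):0.25,"
    "((Mesostigma:0.35,Chlorokybus:0.30):0.08,"
    "(Klebsormidium:0.35,"
    "((Penium:0.30,Spirogyra:0.30):0.10,"
    "((Coleochaete:0.25,Chaetosphaeridium:0.30):0.08,"
    "(Nitella:0.30,"
    "(Physcomitrella:0.25,(Oryza:0.20,(Arabidopsis:0.15,Populus:0.15):0.05):0.05):0.10"
    "):0.06):0.05):0.06):0.07):0.15);"
)

# per-taxon gene-retention probabilities for the transcriptome taxa,
# matched to the observed per-taxon gene representation of the study
DEFAULT_OCCUPANCY = {
    "Chlorokybus": 1.0,
    "Chaetosphaeridium": 0.65625,
    "Coleochaete": 0.8875,
    "Klebsormidium": 1.0,
    "Mesostigma": 0.1125,
    "Nitella": 1.0,
    "Penium": 0.8875,
    "Spirogyra": 0.68125,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    species_tree: Optional[PhyloTree] = None
    n_genes: int = 100
    gene_length: int = 150
    dup_rate: float = 0.02      # duplications per branch-length unit
    loss_rate: float = 0.02     # losses per branch-length unit
    occupancy_profile: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPANCY)
    )
    biased_fraction: float = 0.15
    bias_rate_scale: float = 3.0   # rate acceleration in the shifted lineage
    incongruent_fraction: float = 0.10
    alternative_topology: Optional[PhyloTree] = None
    gamma_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.species_tree is None:
            self.species_tree = read_newick(DEFAULT_SPECIES_TREE)
        if self.alternative_topology is None:
            self.alternative_topology = read_newick(ALTERNATIVE_TOPOLOGY)
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        for name, frac in (
            ("biased_fraction", self.biased_fraction),
            ("incongruent_fraction", self.incongruent_fraction),
        ):
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for taxon, p in self.occupancy_profile.items():
            if not 0 <= p <= 1:
                raise ValueError(f"occupancy for {taxon} must be in [0, 1]")


@dataclass
class TruthBundle:
    """Complete ground truth of one synthetic study."""

    species_tree: PhyloTree
    gene_trees: dict[str, PhyloTree]
    ortholog_map: dict[str, set[str]]
    paralog_ids: set[str]
    biased_genes: set[str]
    incongruent_genes: set[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "species_tree": self.species_tree.newick(),
            "gene_trees": {g: t.newick() for g, t in sorted(self.gene_trees.items())},
            "ortholog_map": {g: sorted(v) for g, v in sorted(self.ortholog_map.items())},
            "paralog_ids": sorted(self.paralog_ids),
            "biased_genes": sorted(self.biased_genes),
            "incongruent_genes": sorted(self.incongruent_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        payload = json.loads(Path(path).read_text())
        return cls(
            species_tree=read_newick(payload["species_tree"]),
            gene_trees={g: read_newick(t) for g, t in payload["gene_trees"].items()},
            ortholog_map={g: set(v) for g, v in payload["ortholog_map"].items()},
            paralog_ids=set(payload["paralog_ids"]),
            biased_genes=set(payload["biased_genes"]),
            incongruent_genes=set(payload["incongruent_genes"]),
        )


# ---------------------------------------------------------------------- #
# gene-tree simulation (duplication/loss on the species tree)
# ---------------------------------------------------------------------- #
def _evolve_lineage(sp_node: Node, remaining: float, dup: float, loss: float,
                    rng, is_paralog: bool) -> Optional[Node]:
    """One gene lineage travelling toward ``sp_node`` with ``remaining``
    branch length still ahead; duplication copies the whole subtree from
    the duplication point.  Returns a gene-(sub)tree node or None if the
    lineage leaves no surviving descendants."""
    t_loss = rng.exponential(1.0 / loss) if loss > 0 else math.inf
    t_dup = rng.exponential(1.0 / dup) if dup > 0 else math.inf
    if t_loss < min(t_dup, remaining):
        return None
    if t_dup < remaining:
        original = _evolve_lineage(sp_node, remaining - t_dup, dup, loss, rng, is_paralog)
        copy = _evolve_lineage(sp_node, remaining - t_dup, dup, loss, rng, True)
        survivors = [x for x in (original, copy) if x is not None]
        if not survivors:
            return None
        if len(survivors) == 1:
            survivors[0].length += t_dup
            return survivors[0]
        joint = Node(length=t_dup)
        for s in survivors:
            joint.add_child(s)
        return joint
    if sp_node.is_leaf:
        leaf = Node(name=sp_node.name, length=remaining)
        leaf.support = 1.0 if is_paralog else None  # transient paralog marker
        return leaf
    children = [
        _evolve_lineage(c, c.length, dup, loss, rng, is_paralog)
        for c in sp_node.children
    ]
    alive = [x for x in children if x is not None]
    if not alive:
        return None
    if len(alive) == 1:
        alive[0].length += remaining
        return alive[0]
    node = Node(length=remaining)
    for c in alive:
        node.add_child(c)
    return node


def _iter_leaves(node: Node):
    if node.is_leaf:
        yield node
        return
    for child in node.children:
        yield from _iter_leaves(child)


def _simulate_one_gene_tree(species_tree: PhyloTree, dup: float, loss: float, rng):
    root = Node()
    for child in species_tree.root.children:
        lineage = _evolve_lineage(child, child.length, dup, loss, rng, False)
        if lineage is not None:
            root.add_child(lineage)
    if not root.children:
        return None
    if len(root.children) == 1:
        root = root.children[0]
        root.parent = None
        root.length = 0.0
    return root


def simulate_gene_trees(
    cfg: SimulationConfig,
) -> tuple[dict[str, PhyloTree], dict[str, dict[str, bool]], set[str], set[str]]:
    """Simulate per-gene trees with duplication/loss, occupancy dropout and
    topological incongruence.

    Returns (gene_trees, presence, incongruent_genes, paralog_ids).  Gene
    tree leaves are renamed to sequence ids: the surviving original copy
    of a taxon keeps ``<taxon>|<gene>``; extra (duplicated) copies get a
    ``.p<k>`` suffix and are recorded as paralogs.  Genes left with fewer
    than four leaves are discarded and logged.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    names = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
    incongruent = {g for g in names if rng.random() < cfg.incongruent_fraction}
    gene_trees: dict[str, PhyloTree] = {}
    presence: dict[str, dict[str, bool]] = {}
    paralog_ids: set[str] = set()
    n_discarded = 0
    for gene in names:
        base = cfg.alternative_topology if gene in incongruent else cfg.species_tree
        root = _simulate_one_gene_tree(base, cfg.dup_rate, cfg.loss_rate, rng)
        tree = None
        if root is not None and root.children:
            # rename leaves to sequence ids (duplicate copies get .p<k>)
            # before building the tree, so leaf labels are unique
            per_taxon_copies: dict[str, int] = {}
            for leaf in _iter_leaves(root):
                taxon = leaf.name
                flagged_paralog = leaf.support == 1.0
                leaf.support = None
                if taxon not in per_taxon_copies and not flagged_paralog:
                    per_taxon_copies[taxon] = 0
                    leaf.name = make_id(taxon, gene)
                else:
                    k = per_taxon_copies.get(taxon, 0) + 1
                    per_taxon_copies[taxon] = k
                    leaf.name = make_id(taxon, f"{gene}.p{k}")
            tree = PhyloTree(root)
            # occupancy dropout: transcriptome taxa lose the whole gene
            dropped = {
                taxon
                for taxon, p in cfg.occupancy_profile.items()
                if rng.random() >= p
            }
            if dropped:
                keep = [
                    lf.name
                    for lf in tree.leaves()
                    if lf.name.split("|")[0] not in dropped
                ]
                tree = tree.prune_to(keep) if len(keep) >= 4 else None
        if tree is None or len(tree.leaves()) < 4:
            n_discarded += 1
            log_stage("simulate", 1, 0, f"{gene} discarded (<4 leaves)")
            continue
        for leaf in tree.leaves():
            if ".p" in leaf.name.split("|")[1]:
                paralog_ids.add(leaf.name)
        gene_trees[gene] = tree
        presence[gene] = {
            taxon: any(lf.name.startswith(taxon + "|") for lf in tree.leaves())
            for taxon in cfg.species_tree.leaf_names()
        }
    log_stage("simulate", cfg.n_genes, len(gene_trees), f"{n_discarded} discarded")
    return gene_trees, presence, incongruent & set(gene_trees), paralog_ids


# ---------------------------------------------------------------------- #
# sequence evolution
# ---------------------------------------------------------------------- #
def evolve_sequences(
    tree: PhyloTree,
    length: int,
    model: SubstitutionModel,
    seed: int,
    shift_model: Optional[SubstitutionModel] = None,
    shift_node: Optional[Node] = None,
) -> MultipleAlignment:
    """Evolve an ungapped alignment on ``tree`` under ``model``.

    Root states are drawn from the equilibrium frequencies; each site is
    assigned one discrete-gamma rate category (uniformly, matching the
    equal-probability discretization) and evolved along every branch by
    the category's transition probabilities.

    When ``shift_model``/``shift_node`` are given, the branch into
    ``shift_node`` and everything below it evolve under ``shift_model``
    instead — compositional heterogeneity restricted to one lineage, the
    violation of stationarity the chi-square composition filter targets.
    """
    if length <= 0:
        raise ValueError("sequence length must be positive")
    if len(tree.leaves()) < 2:
        raise ValueError("tree must have at least two leaves")
    rng = np.random.default_rng(seed)
    rates = model.category_rates()
    cats = rng.integers(len(rates), size=length)
    rows: dict[str, str] = {}

    def descend(node: Node, states: np.ndarray, active: SubstitutionModel) -> None:
        for child in node.children:
            child_model = (
                shift_model
                if shift_model is not None and child is shift_node
                else active
            )
            child_states = np.empty(length, dtype=np.int64)
            P_all = child_model.transition_matrices(child.length)
            for k in range(len(rates)):
                idx = np.nonzero(cats == k)[0]
                if idx.size == 0:
                    continue
                cum = np.cumsum(P_all[k], axis=1)
                u = rng.random(idx.size)
                child_states[idx] = (u[:, None] > cum[states[idx]]).sum(axis=1)
            if child.is_leaf:
                rows[child.name] = "".join(AMINO_ACIDS[s] for s in child_states)
            else:
                descend(child, child_states, child_model)

    root_states = rng.choice(20, size=length, p=model.frequencies)
    start = tree.root
    if start.is_leaf:  # 2-leaf tree parsed as (A,B);
        raise ValueError("degenerate tree")
    descend(start, root_states, model)
    return MultipleAlignment(rows)


def skewed_frequencies(rng, peak: float = 0.30) -> np.ndarray:
    """Composition-bias frequency vector: one residue at ``peak``, rest uniform."""
    freqs = np.full(20, (1.0 - peak) / 19.0)
    freqs[int(rng.integers(20))] = peak
    return freqs


# ---------------------------------------------------------------------- #
# full study
# ---------------------------------------------------------------------- #
def generate_study(
    cfg: SimulationConfig, outdir: Optional[str | Path] = None
) -> tuple[TruthBundle, dict[str, list[SeqRecord]], dict[str, MultipleAlignment]]:
    """Generate the whole synthetic study.

    Returns (truth, per-taxon records, per-gene true alignments); when
    ``outdir`` is given, also writes one FASTA per taxon (references under
    ``references/``, unigene sets under ``transcriptomes/``) plus a
    ``truth.json`` sidecar.
    """
    gene_trees, presence, incongruent, paralog_ids = simulate_gene_trees(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    biased = {g for g in sorted(gene_trees) if rng.random() < cfg.biased_fraction}

    base_model = lg_model(cfg.gamma_alpha)
    taxa = cfg.species_tree.leaf_names()
    per_taxon: dict[str, list[SeqRecord]] = {t: [] for t in taxa}
    alignments: dict[str, MultipleAlignment] = {}
    ortholog_map: dict[str, set[str]] = {}
    seed_root = np.random.SeedSequence([cfg.seed, 3])
    gene_seeds = seed_root.generate_state(len(gene_trees))
    for gi, gene in enumerate(sorted(gene_trees)):
        tree = gene_trees[gene]
        shift_model = shift_node = None
        if gene in biased:
            # compositional heterogeneity: one lineage drifts toward a
            # skewed equilibrium (stationarity violation, not a gene-wide
            # frequency change which would be invisible to the filter)
            shift_model = SubstitutionModel(
                name="LG+bias",
                exchangeabilities=base_model.exchangeabilities,
                frequencies=skewed_frequencies(rng),
                gamma_alpha=cfg.gamma_alpha,
            )
            internals = [
                n
                for n in tree.postorder()
                if not n.is_leaf and n is not tree.root
            ]
            shift_node = (
                internals[int(rng.integers(len(internals)))]
                if internals
                else tree.leaves()[0]
            )
            # compositional shifts ride on rate acceleration in that
            # lineage; written into the gene tree so the truth reflects it
            stack = [shift_node]
            while stack:
                nd = stack.pop()
                nd.length *= cfg.bias_rate_scale
                stack.extend(nd.children)
        aln = evolve_sequences(
            tree,
            cfg.gene_length,
            base_model,
            int(gene_seeds[gi] % (2**31)),
            shift_model=shift_model,
            shift_node=shift_node,
        )
        alignments[gene] = aln
        ortholog_map[gene] = set()
        for seq_id, residues in aln.rows.items():
            taxon = seq_id.split("|")[0]
            per_taxon[taxon].append(SeqRecord(seq_id, residues))
            if seq_id not in paralog_ids:
                ortholog_map[gene].add(seq_id)

    truth = TruthBundle(
        species_tree=cfg.species_tree,
        gene_trees=gene_trees,
        ortholog_map=ortholog_map,
        paralog_ids=paralog_ids,
        biased_genes=biased,
        incongruent_genes=incongruent,
    )
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "references").mkdir(parents=True, exist_ok=True)
        (outdir / "transcriptomes").mkdir(parents=True, exist_ok=True)
        for taxon, records in per_taxon.items():
            if not records:  # a taxon can lose every gene at low occupancy
                continue
            sub = "references" if taxon in REFERENCE_TAXA else "transcriptomes"
            write_fasta(sorted(records, key=lambda r: r.id), outdir / sub / f"{taxon}.fasta")
        truth.to_json(outdir / "truth.json")
    return truth, per_taxon, alignments
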