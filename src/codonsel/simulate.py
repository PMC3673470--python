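"""Synthetic codon alignments, trees and disease-mutation fixtures.

The generator is the exact forward counterpart of the inference models:
site classes are drawn i.i.d. across sites from the model's mixture
weights, the root codon from the equilibrium frequencies, and states
evolve down the tree through the class- and branch-appropriate transition
matrices (foreground branches use the foreground omega for branch-site
and two-ratio variants).  Every fixture records its seed and ground
truth, so parameter recovery, test calibration and the conservation
pipeline can all be checked end to end without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .codons import MISSING, CodonAlignment, CodonFrequencies, codon_frequencies
from .likelihood import MixtureEngine
from .models import OmegaModel
from .trees import PhyloTree, write_newick

__all__ = [
    "SimulationTruth",
    "random_tree",
    "simulate_alignment",
    "simulate_study",
]


@dataclass
class SimulationTruth:
    """Ground truth of one simulated alignment."""

    site_class: np.ndarray       # class index per site
    omega_back: np.ndarray       # true background omega per site
    omega_fore: np.ndarray       # true foreground omega per site
    model: OmegaModel
    seed: int

    @property
    def lowest_class_sites(self) -> np.ndarray:
        """Site indices whose true class is the lowest-omega class."""
        omegas = np.array([c.omega for c in self.model.site_classes()])
        return np.flatnonzero(self.site_class == int(np.argmin(omegas)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site": np.arange(1, self.site_class.size + 1),
                "true_class": self.site_class,
                "true_omega_back": self.omega_back,
                "true_omega_fore": self.omega_fore,
            }
        )


def random_tree(
    n_taxa: int,
    seed: int | np.random.Generator = 0,
    mean_branch: float = 0.15,
    labels: list[str] | None = None,
) -> PhyloTree:
    """A random binary topology with exponential branch lengths.

    Lineages are joined in random pairs (a Kingman-style topology); each
    branch gets an independent Exponential(``mean_branch``) length.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{i + 1:02d}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("label count must match n_taxa")
    n_nodes = 2 * n_taxa - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    lengths = np.zeros(n_nodes)
    node_labels: list[str | None] = list(labels) + [None] * (n_taxa - 1)
    active = list(range(n_taxa))
    nxt = n_taxa
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        for ch in (a, b):
            parent[ch] = nxt
            children[nxt].append(ch)
            lengths[ch] = rng.exponential(mean_branch)
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    root = active[0]
    fg = np.zeros(n_nodes, dtype=bool)
    return PhyloTree(parent, children, lengths, fg, node_labels, root)


def simulate_alignment(
    tree: PhyloTree,
    model: OmegaModel,
    n_codons: int,
    pi: CodonFrequencies | None = None,
    seed: int = 0,
    missing_fraction: float = 0.0,
    code=None,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve a codon alignment on ``tree`` under ``model``.

    Deterministic given identical inputs and ``seed``.  With
    ``missing_fraction > 0`` exactly ``round(fraction * cells)`` of the
    (taxon, site) cells are masked to MISSING, mimicking ambiguity in real
    alignments.
    """
    if n_codons < 0:
        raise ValueError("n_codons must be non-negative")
    rng = np.random.default_rng(seed)
    if pi is None:
        pi = codon_frequencies(None, "uniform", code=code)
    classes = model.site_classes()
    engine = MixtureEngine(model.kappa, classes, pi, code=code)
    leaves = tree.leaves
    labels = [tree.labels[v] for v in leaves]
    if n_codons == 0:
        aln = CodonAlignment(labels, np.zeros((len(labels), 0), np.int32),
                             engine.background[0].code)
        truth = SimulationTruth(np.array([], int), np.array([]), np.array([]), model, seed)
        return aln, truth

    weights = engine.weights
    site_class = rng.choice(len(classes), size=n_codons, p=weights)
    pvec = np.asarray(pi.pi, float)
    states = {tree.root: rng.choice(pvec.size, size=n_codons, p=pvec / pvec.sum())}
    # precompute per (class, branch) cumulative transition rows lazily
    for node in reversed(tree.postorder):       # preorder: parents first
        if node == tree.root:
            continue
        parent_states = states[tree.parent[node]]
        child = np.empty(n_codons, dtype=np.int64)
        for k in range(len(classes)):
            sites = np.flatnonzero(site_class == k)
            if sites.size == 0:
                continue
            back, fore = engine.matrices(k)
            Q = fore if tree.foreground[node] else back
            P = Q.transition(tree.lengths[node])
            cum = np.cumsum(P, axis=1)
            u = rng.random(sites.size)
            rows = cum[parent_states[sites]]
            child[sites] = (rows >= u[:, None]).argmax(axis=1)
        states[node] = child
    mat = np.stack([states[v] for v in leaves]).astype(np.int32)
    if missing_fraction > 0:
        # exact count: round(fraction * cells) cells masked, without replacement
        n_cells = mat.size
        n_mask = int(round(missing_fraction * n_cells))
        flat = rng.choice(n_cells, size=n_mask, replace=False)
        mat.reshape(-1)[flat] = MISSING
    aln = CodonAlignment(labels, mat, engine.background[0].code)
    truth = SimulationTruth(
        site_class=site_class,
        omega_back=np.array([classes[k].omega for k in site_class]),
        omega_fore=np.array([classes[k].fore for k in site_class]),
        model=model,
        seed=seed,
    )
    return aln, truth


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _synthesize_dams(
    aln: CodonAlignment,
    truth: SimulationTruth,
    gene: str,
    count: int,
    enrichment: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw DAM positions enriched at truly conserved (lowest-class) sites."""
    ref = aln.reference_name or aln.taxa[0]
    ref_states = aln.row(ref)
    observed = np.flatnonzero(ref_states != MISSING)
    if observed.size == 0 or count == 0:
        return pd.DataFrame(columns=[
            "gene", "protein_position", "ref_aa", "alt_aa", "source_id", "external_score"])
    low = set(truth.lowest_class_sites.tolist())
    is_low = np.array([s in low for s in observed])
    p = np.zeros(observed.size)
    if is_low.any():
        p[is_low] += enrichment / is_low.sum()
    p += (1.0 - enrichment) / observed.size
    p /= p.sum()
    count = min(count, int((p > 0).sum()))
    chosen = rng.choice(observed, size=count, replace=False, p=p)
    chosen.sort()
    aa = aln.code.amino_acids()
    # protein position = rank among observed reference codons (1-based)
    rank = {int(s): i + 1 for i, s in enumerate(observed)}
    rows = []
    for n, s in enumerate(chosen):
        ref_aa = aa[ref_states[s]]
        alt_aa = rng.choice([a for a in _AA if a != ref_aa])
        rows.append(
            {
                "gene": gene,
                "protein_position": rank[int(s)],
                "ref_aa": ref_aa,
                "alt_aa": alt_aa,
                "source_id": f"{gene}_dam{n + 1:03d}",
                "external_score": round(float(rng.uniform(0.5, 1.0)), 3),
            }
        )
    return pd.DataFrame(rows)


def simulate_study(manifest: dict, seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Generate the full fixture bundle a study manifest describes.

    Every entry of ``manifest["genes"]`` needs ``id`` plus optional
    ``n_taxa``, ``n_codons``, ``model`` (variant and parameter overrides),
    ``dams`` (``count``, ``enrichment``) and ``foreground`` (True tags one
    random internal stem branch).  Returns a bundle mapping gene id to
    ``{alignment, tree, truth, dams}``; with ``out_dir`` the standard
    layout (<gene>/alignment.fasta, tree.nwk, truth.tsv, dams.tsv and a
    manifest.echo) is also written.
    """
    genes = manifest.get("genes") or manifest.get("datasets")
    if not genes:
        raise KeyError("manifest has no 'genes' (or 'datasets') list")
    bundle: dict[str, dict] = {}
    for g, gene in enumerate(genes):
        if "id" not in gene:
            raise KeyError(f"gene entry {g} missing required key 'id'")
        gid = gene["id"]
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, g]))
        sub_seed = int(rng.integers(2**31 - 1))
        n_taxa = int(gene.get("n_taxa", 12))
        n_codons = int(gene.get("n_codons", 300))
        model_kw = dict(gene.get("model", {}))
        variant = model_kw.pop("variant", "M8")
        model = OmegaModel(variant=variant, **model_kw)
        tree = random_tree(n_taxa, rng, mean_branch=float(gene.get("mean_branch", 0.15)))
        if gene.get("foreground") or model.uses_foreground:
            internal = [v for v in range(tree.n_nodes)
                        if tree.children[v] and v != tree.root]
            tree.foreground[rng.choice(internal)] = True
        aln, truth = simulate_alignment(
            tree, model, n_codons, seed=sub_seed,
            missing_fraction=float(gene.get("missing_fraction", 0.0)),
        )
        ref = gene.get("reference", aln.taxa[0])
        if ref not in aln.taxa:
            raise KeyError(f"gene {gid!r}: reference taxon {ref!r} not in alignment")
        aln.reference_name = ref
        dam_cfg = gene.get("dams", {})
        dams = _synthesize_dams(
            aln, truth, gid,
            count=int(dam_cfg.get("count", 0)),
            enrichment=float(dam_cfg.get("enrichment", 0.9)),
            rng=rng,
        )
        bundle[gid] = {"alignment": aln, "tree": tree, "truth": truth, "dams": dams}
    if out_dir is not None:
        out = Path(out_dir)
        for gid, item in bundle.items():
            gdir = out / gid
            gdir.mkdir(parents=True, exist_ok=True)
            (gdir / "alignment.fasta").write_text(item["alignment"].to_fasta())
            (gdir / "tree.nwk").write_text(write_newick(item["tree"]) + "\n")
            truth_path = gdir / "truth.tsv"
            with open(truth_path, "w") as fh:
                fh.write(f"# seed={item['truth'].seed}\n")
                item["truth"].to_frame().to_csv(fh, sep="\t", index=False)
            item["dams"].to_csv(gdir / "dams.tsv", sep="\t", index=False)
        (out / "manifest.echo").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return bundle
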