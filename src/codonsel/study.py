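"""End-to-end study orchestration: fits, LRTs, FDR, posteriors, conservation.

A *study manifest* (a plain mapping, YAML-serializable) declares data
sets, the tests to run on each, hypothesis families, thresholds and
seeds.  :func:`run_study` executes the whole chain — maximum-likelihood
fits, likelihood-ratio tests, family-wise multiple-testing correction,
empirical-Bayes site posteriors, conservation profiles and
disease-mutation mapping — and emits a TSV report bundle plus a run log.

Data sets either point at files (``alignment``/``tree`` paths, optional
``dams`` TSV) or carry simulation settings, in which case the fixtures
are generated on the fly with the study seed.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .codons import read_codon_alignment
from .conservation import (
    conservation_profile,
    dam_overlap_summary,
    map_dams,
    read_dam_table,
)
from .models import CodonModel, FitOptions, embed_null, lrt
from .multitest import ManifestError, build_test_families, enumerate_tests
from .simulate import simulate_study
from .trees import read_clade_file, read_newick

__all__ = [
    "TESTS",
    "load_manifest",
    "full_study_design",
    "default_study_manifest",
    "run_study",
]

logger = logging.getLogger(__name__)

#: Supported test names and the (null, alternative) variants each compares.
TESTS = {
    "site_m7m8": ("M7", "M8"),
    "site_m8m8a": ("M8a", "M8"),
    "branch_site": ("BranchSiteA_null", "BranchSiteA"),
    "two_ratio": ("M0", "TwoRatio"),
}

DEFAULT_THRESHOLDS = {"pp_threshold": 0.95, "low_omega": 0.25, "ci_threshold": 0.9}


def load_manifest(source) -> dict:
    """Load a manifest from a mapping, a YAML string, or a file path."""
    if isinstance(source, dict):
        manifest = dict(source)
    else:
        path = Path(source)
        if path.exists():
            manifest = yaml.safe_load(path.read_text())
        else:
            manifest = yaml.safe_load(str(source))
        if not isinstance(manifest, dict):
            raise ManifestError("manifest must be a mapping")
    manifest.setdefault("thresholds", {})
    for k, v in DEFAULT_THRESHOLDS.items():
        manifest["thresholds"].setdefault(k, v)
    manifest.setdefault("correction", "BH")
    for ds in manifest.get("datasets", []):
        bad = [t for t in ds.get("tests", []) if t not in TESTS]
        if bad:
            raise ManifestError(f"dataset {ds.get('id')!r}: unknown tests {bad}")
    # raises on overlapping/undefined declarations
    build_test_families(manifest)
    return manifest


def full_study_design(
    n_taxa: int = 12, n_codons: int = 300, dams_per_gene: int = 0
) -> dict:
    """A 19-data-set design with the canonical 50-test / 13-family layout.

    Nine single-region loci carry the two site tests each (families A–I);
    a three-region locus contributes family J (its longest region) and
    family M (all six of its tests, overlapping J); a fourth locus is
    analysed as a whole, per region with lineage tests (family K, 14
    tests), and per region again in a focal subclade (family L, 12
    tests).
    """
    datasets: list[dict] = []
    families: dict[str, list[list[str]]] = {}
    site = ["site_m7m8", "site_m8m8a"]
    lineage = ["branch_site", "two_ratio"]

    def add(ds_id: str, tests: list[str], foreground: bool = False) -> None:
        datasets.append(
            {
                "id": ds_id,
                "tests": list(tests),
                "n_taxa": n_taxa,
                "n_codons": n_codons,
                "model": {"variant": "M8", "p0": 0.9, "omega_s": 2.0,
                          "beta_p": 0.2, "beta_q": 1.5},
                "dams": {"count": dams_per_gene, "enrichment": 0.9},
                "foreground": foreground,
            }
        )

    for g, fam in enumerate("ABCDEFGHI", start=1):
        ds = f"g{g:02d}"
        add(ds, site)
        families[fam] = [[ds, t] for t in site]
    # three-region locus: family J covers the longest region, family M all three
    regions10 = [f"g10_r{i}" for i in (1, 2, 3)]
    for ds in regions10:
        add(ds, site)
    families["J"] = [["g10_r3", t] for t in site]
    families["M"] = [[ds, t] for ds in regions10 for t in site]
    # fourth locus: whole gene + three regions with lineage tests (family K)
    add("g11", site)
    regions11 = [f"g11_r{i}" for i in (1, 2, 3)]
    for ds in regions11:
        add(ds, site + lineage, foreground=True)
    families["K"] = [["g11", t] for t in site] + [
        [ds, t] for ds in regions11 for t in site
    ] + [[ds, t] for ds in regions11 for t in lineage]
    # the same three regions restricted to a focal subclade (family L)
    clades = [f"g11_r{i}_clade" for i in (1, 2, 3)]
    for ds in clades:
        add(ds, site + lineage, foreground=True)
    families["L"] = [[ds, t] for ds in clades for t in site] + [
        [ds, t] for ds in clades for t in lineage
    ]
    return {
        "datasets": datasets,
        "families": families,
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "correction": "BH",
    }


def default_study_manifest(
    n_genes: int = 3,
    n_taxa: int = 12,
    n_codons: int = 300,
    dams_per_gene: int = 10,
    enrichment: float = 0.9,
) -> dict:
    """A small synthetic study: M8-generated genes with enriched DAM tables.

    Defaults mirror the package's standard synthetic conditions: 12-taxon
    trees, 300 codons, an M8 mixture with a strongly purifying beta
    component (p = 0.2, q = 1.5), a 10% positive class at omega_s = 2,
    and DAM positions drawn with 0.9 enrichment toward the lowest-omega
    class.  Each gene carries the two site tests in its own family.
    """
    datasets = []
    families = {}
    for g in range(1, n_genes + 1):
        ds = f"gene{g:02d}"
        datasets.append(
            {
                "id": ds,
                "tests": ["site_m7m8", "site_m8m8a"],
                "n_taxa": n_taxa,
                "n_codons": n_codons,
                "model": {"variant": "M8", "p0": 0.9, "omega_s": 2.0,
                          "beta_p": 0.2, "beta_q": 1.5},
                "dams": {"count": dams_per_gene, "enrichment": enrichment},
            }
        )
        families[f"F{g}"] = [[ds, "site_m7m8"], [ds, "site_m8m8a"]]
    return {
        "datasets": datasets,
        "families": families,
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "correction": "BH",
    }


def _load_dataset(ds: dict, bundle: dict | None):
    """Alignment, tree and optional DAM table for one data set."""
    if "alignment" in ds:
        aln_path, tree_path = Path(ds["alignment"]), Path(ds["tree"])
        for p in (aln_path, tree_path):
            if not p.exists():
                raise FileNotFoundError(f"dataset {ds['id']!r}: missing input {p}")
        aln = read_codon_alignment(
            aln_path.read_text(), reference_name=ds.get("reference")
        )
        tree = read_newick(tree_path.read_text())
        if ds.get("foreground_clades"):
            spec = ds["foreground_clades"]
            if isinstance(spec, str):           # path to a plain-text clade file
                clades = read_clade_file(Path(spec).read_text())
            else:
                clades = [set(c) for c in spec]
            tree = tree.tag_clades(clades)
        dams = None
        if ds.get("dams_table"):
            dam_path = Path(ds["dams_table"])
            if not dam_path.exists():
                raise FileNotFoundError(f"dataset {ds['id']!r}: missing input {dam_path}")
            dams = read_dam_table(str(dam_path))
        return aln, tree, dams
    if bundle is None or ds["id"] not in bundle:
        raise ManifestError(f"dataset {ds['id']!r} has neither file paths nor simulation output")
    item = bundle[ds["id"]]
    dams = item["dams"] if len(item["dams"]) else None
    return item["alignment"], item["tree"], dams


def _write_tsv(path: Path, df: pd.DataFrame, meta: list[str]) -> None:
    with open(path, "w") as fh:
        for line in meta:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def run_study(
    manifest, out_dir: str | Path | None = None, seed: int = 0,
    n_starts: int = 2, posterior_method: str = "BEB",
) -> dict:
    """Execute a full study and return (and optionally write) its reports.

    Returns a bundle with the ``tests`` table (one row per family
    membership), per-data-set conservation ``profiles`` and site tables,
    the mapped ``dams`` table with its ``dam_summary``, and the raw
    ``fits``.  With ``out_dir``, the TSV bundle, the manifest echo and a
    run log are written there.  Identical manifest and seed reproduce
    identical table rows.
    """
    manifest = load_manifest(manifest)
    thresholds = manifest["thresholds"]
    correction = manifest.get("correction", "BH")
    needs_sim = [ds for ds in manifest["datasets"] if "alignment" not in ds]
    bundle = None
    if needs_sim:
        bundle = simulate_study({"genes": needs_sim}, seed=seed)

    fits: dict[tuple[str, str], object] = {}
    lrt_results: dict[tuple[str, str], object] = {}
    profiles: dict[str, pd.DataFrame] = {}
    profile_objs: dict[str, object] = {}
    mapped_frames: list[pd.DataFrame] = []
    log_lines = [
        f"codonsel {__version__} | python {sys.version.split()[0]} | "
        f"numpy {np.__version__} | seed {seed}",
        f"correction={correction} thresholds={thresholds}",
    ]

    for d_i, ds in enumerate(manifest["datasets"]):
        ds_id = ds["id"]
        aln, tree, dams = _load_dataset(ds, bundle)
        ds_seed = int(np.random.SeedSequence([seed & 0x7FFFFFFF, d_i]).generate_state(1)[0] % (2**31 - 1))
        opts = FitOptions(n_starts=n_starts, seed=ds_seed, branch_mode="m0")
        tests = ds.get("tests", [])
        variants = {"M0"}
        for t in tests:
            variants.update(TESTS[t])
        if any(t in ("site_m7m8", "site_m8m8a") for t in tests):
            variants.add("M8")      # posteriors always come from the M8 fit
        m0 = CodonModel(aln, tree, "M0").fit(opts, branch_mode="joint", n_starts=1)
        fits[(ds_id, "M0")] = m0
        log_lines.append(
            f"{ds_id}: M0 lnL={m0.llf:.4f} converged={m0.converged} "
            f"tree_length={float(m0.branch_lengths.sum()):.3f}"
        )
        # nulls first so each alternative can warm-start from its null's MLE,
        # which makes the nesting inequalities hold by construction
        order = ["M7", "M8a", "M8", "BranchSiteA_null", "BranchSiteA", "TwoRatio"]
        warm_from = {"M8": ["M7", "M8a"], "BranchSiteA": ["BranchSiteA_null"],
                     "TwoRatio": ["M0"]}
        for variant in order:
            if variant not in variants:
                continue
            extra = [
                embed_null(fits[(ds_id, nv)].spec, variant)
                for nv in warm_from.get(variant, [])
                if (ds_id, nv) in fits
            ]
            res = CodonModel(aln, tree, variant).fit(
                opts, m0_result=m0, extra_starts=extra
            )
            fits[(ds_id, variant)] = res
            flag = "" if res.converged else "  ** NOT CONVERGED"
            log_lines.append(f"{ds_id}: {variant} lnL={res.llf:.4f}{flag}")
        for t in tests:
            null_v, alt_v = TESTS[t]
            lrt_results[(ds_id, t)] = lrt(fits[(ds_id, null_v)], fits[(ds_id, alt_v)],
                                          test_name=t)
        # conservation profile from the M8 fit, regardless of LRT significance
        if (ds_id, "M8") in fits:
            m8 = fits[(ds_id, "M8")]
            post = m8.site_posteriors(method=posterior_method)
            prof = conservation_profile(
                post, aln, gene=ds_id,
                pp_threshold=thresholds["pp_threshold"],
                low_omega=thresholds["low_omega"],
            )
            profile_objs[ds_id] = prof
            frame = prof.to_frame()
            pp_cols = pd.DataFrame(
                post.PP, columns=[f"pp_class{k + 1}" for k in range(post.n_classes)]
            )
            positive = (post.PP > thresholds["pp_threshold"]) & (post.class_omegas > 1.0)[None, :]
            frame = pd.concat([frame, pp_cols], axis=1)
            frame["positive_site"] = positive.any(axis=1)
            profiles[ds_id] = frame
            if dams is not None:
                mapped_frames.append(map_dams(dams, aln, prof))

    families = build_test_families(manifest)
    p_by_test = {k: v.p_raw for k, v in lrt_results.items()}
    rows = []
    for fam in families:
        fam.attach(p_by_test, method=correction)
        for (ds_id, t), p_raw, p_adj in zip(fam.member_tests, fam.p_raw, fam.p_adj):
            r = lrt_results[(ds_id, t)]
            null_v, alt_v = TESTS[t]
            rows.append(
                {
                    "family_id": fam.family_id,
                    "dataset": ds_id,
                    "test": t,
                    "lnL_null": fits[(ds_id, null_v)].llf,
                    "lnL_alt": fits[(ds_id, alt_v)].llf,
                    "stat": r.stat,
                    "df": r.df,
                    "p_raw": p_raw,
                    "p_adj": p_adj,
                }
            )
    tests_df = pd.DataFrame(
        rows, columns=["family_id", "dataset", "test", "lnL_null", "lnL_alt",
                       "stat", "df", "p_raw", "p_adj"],
    )
    mapped = (
        pd.concat(mapped_frames, ignore_index=True)
        if mapped_frames else pd.DataFrame()
    )
    summary = dam_overlap_summary(mapped, thresholds["ci_threshold"]) if len(mapped) else pd.DataFrame()

    report = {
        "tests": tests_df,
        "profiles": profiles,
        "profile_objects": profile_objs,
        "dams": mapped,
        "dam_summary": summary,
        "fits": fits,
        "families": families,
        "log": log_lines,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = [f"codonsel {__version__}", f"seed={seed}", f"correction={correction}"]
        _write_tsv(out / "tests.tsv", tests_df, meta)
        for ds_id, frame in profiles.items():
            _write_tsv(out / f"sites_{ds_id}.tsv", frame, meta)
        if len(mapped):
            _write_tsv(out / "dams_mapped.tsv", mapped, meta)
            _write_tsv(out / "dam_summary.tsv", summary, meta)
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        (out / "manifest.echo").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return report
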