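"""Reproducible end-to-end runs on synthetic data.

RunConfig holds every stage parameter plus one global seed; each stochastic
stage receives a seed derived by hashing (global seed, stage name), so
adding a stage never perturbs the others.  run_pipeline executes the stages
in dependency order — cohort → W-scores → spatial association → threshold
sweep → set statistics → GU content → co-expression graph → epicentres —
writing every table as TSV plus a manifest with SHA-256 checksums; rerunning
with the same config reproduces the manifest bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, epicentres, genesets, gurepeats, spatial, synthetic, wscore


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters; defaults give a ~1-minute desk-scale demo."""

    seed: int = 0
    n_regions: int = 120
    n_genes: int = 400
    autocorr_scale: float = 0.4
    n_subtypes: int = 3
    n_patients_per_subtype: int = 15
    n_controls: int = 200
    noise_sd: float = 0.5
    planted_per_subtype: int = 8
    planted_r: float = 0.6
    B: int = 200                      # surrogate maps per atrophy map
    q: float = 0.05
    tau: float = 0.2
    theta: float = 0.3                # co-expression binarization
    frac_har: float = 0.12
    frac_cs: float = 0.05
    overlap_enrichment: float = 2.0
    n_seeds: int = 60                 # connectivity library size
    kernel_scale: float = 0.5
    gu_high_weight: float = 0.03
    seq_length: tuple[int, int] = (300, 800)

    def validate(self) -> None:
        if self.B < 1:
            raise ValueError("config error: B must be >= 1")
        if not 0 < self.q < 1:
            raise ValueError("config error: q must be in (0,1)")
        if self.n_regions < 4:
            raise ValueError("config error: n_regions must be >= 4")

    def to_yaml(self, path: Path) -> None:
        d = dataclasses.asdict(self)
        d["seq_length"] = list(d["seq_length"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "seq_length" in d:
            d["seq_length"] = tuple(d["seq_length"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from (global seed, stage name)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _write_tsv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as f:
        f.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(f, sep="\t")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages on synthetic data; returns the run directory."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    config.to_yaml(out / "config.yaml")
    gs = config.seed
    artifacts: dict[str, Path] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        _write_tsv(df, path, cfg_hash)
        artifacts[name] = path

    # --- synthetic inputs -------------------------------------------------
    geom = synthetic.make_geometry(config.n_regions, "sphere",
                                   seed=stage_seed(gs, "geometry"))
    donors = synthetic.make_expression(geom, config.n_genes, config.autocorr_scale,
                                       n_donors=1, seed=stage_seed(gs, "expression"))
    expr = synthetic.average_expression(donors)
    save("expression", expr)

    genes = list(expr.columns)
    catalog, _ = synthetic.make_gene_lists(
        genes, config.frac_har, config.frac_cs, config.overlap_enrichment,
        seed=stage_seed(gs, "gene_lists"))
    for name in ("HAR", "CS"):
        (out / f"genes_{name}.txt").write_text("\n".join(sorted(catalog[name])) + "\n")
        artifacts[f"genes_{name}"] = out / f"genes_{name}.txt"

    library = synthetic.make_connectivity_library(
        geom, config.n_seeds, config.kernel_scale,
        seed=stage_seed(gs, "connectivity"))
    save("connectivity_library", library)

    # --- per-subtype atrophy with planted gene correlates -----------------
    rng = np.random.default_rng(stage_seed(gs, "planting"))
    atrophy_maps: dict[str, pd.Series] = {}
    for s in range(config.n_subtypes):
        name = f"S{s}"
        planted = list(rng.choice(genes, config.planted_per_subtype, replace=False))
        seed_region = str(rng.choice(library.index))
        atrophy = pd.Series(library.loc[seed_region].to_numpy(),
                            index=geom.region_ids)
        expr, _ = synthetic.plant_gene_correlates(
            expr, atrophy, planted, config.planted_r, geom,
            config.autocorr_scale, seed=stage_seed(gs, f"plant:{name}"))
        atrophy_maps[name] = atrophy
    save("expression_planted", expr)

    # --- cohorts, W-scores, spatial association per subtype ---------------
    subtype_tables: dict[str, pd.DataFrame] = {}
    group_wmaps: dict[str, pd.Series] = {}
    assignments: dict[str, pd.DataFrame] = {}
    for name, atrophy in atrophy_maps.items():
        controls, patients, _ = synthetic.make_cohort(
            geom, config.n_controls, config.n_patients_per_subtype, atrophy,
            noise_sd=config.noise_sd, seed=stage_seed(gs, f"cohort:{name}"))
        model = wscore.fit_control_model(controls, list(synthetic.DEFAULT_COVARIATES))
        wmaps = wscore.compute_wmap(patients, model)
        save(f"wmaps_{name}", wmaps)
        gmap = wscore.group_average([wmaps.loc[i] for i in wmaps.index])
        group_wmaps[name] = gmap
        table = spatial.correlate_with_surrogates(
            gmap, expr, geom, config.B, seed=stage_seed(gs, f"surrogates:{name}"),
            q=config.q, tau=config.tau)
        subtype_tables[name] = table
        save(f"correlations_{name}", table)
        assignments[name] = epicentres.assign_epicentres(
            wmaps, library, {i: name for i in wmaps.index})

    # --- sweep, set statistics -------------------------------------------
    if config.n_subtypes >= 3:  # uniqueness index is a 3-subtype construct
        three = dict(list(subtype_tables.items())[:3])
        sweep = genesets.threshold_sweep(three, alpha=config.q)
        save("sweep", sweep.table)

    selected_union = set()
    for t in subtype_tables.values():
        selected_union |= set(t.index[t["selected"]])
    background = set(genes)
    stats_rows = []
    for lst in ("HAR", "CS"):
        if catalog[lst] and selected_union:
            k, p = genesets.fisher_overlap(catalog[lst], selected_union, background)
            stats_rows.append({"test": f"{lst}_vs_correlated", "overlap": k, "p": p})
    stats = pd.DataFrame(stats_rows).set_index("test")
    save("overlap_tests", stats)

    # --- GU content -------------------------------------------------------
    gu_w = {g: (config.gu_high_weight if g in catalog["CS"] else 0.0) for g in genes}
    seqs = synthetic.make_sequences(genes, config.seq_length, gu_w,
                                    seed=stage_seed(gs, "sequences"))
    synthetic.write_fasta(seqs, out / "sequences.fasta")
    artifacts["sequences"] = out / "sequences.fasta"
    profiles = gurepeats.gu_profiles(seqs)
    high_gu = gurepeats.classify_high_gu(profiles)
    save("gu_profiles", profiles)
    (out / "genes_highGU.txt").write_text("\n".join(sorted(high_gu)) + "\n")
    artifacts["genes_highGU"] = out / "genes_highGU.txt"

    # --- co-expression graph ---------------------------------------------
    graph_genes = sorted(selected_union)[:25] or genes[:10]
    r = coexpression.coexpression_matrix(expr, graph_genes)
    graph = coexpression.binarize_and_degree(r, config.theta)
    save("coexpression_degree", graph.degree.to_frame())

    # --- epicentres -------------------------------------------------------
    all_assign = pd.concat(assignments.values())
    save("epicentre_assignments", all_assign)
    freq, _ = epicentres.epicentre_frequency(all_assign)
    save("epicentre_frequency", freq)
    names = sorted(assignments)
    if len(names) >= 2 and catalog["CS"]:
        comp = epicentres.compare_epicentre_expression(
            sorted(catalog["CS"])[:50], assignments[names[0]],
            assignments[names[1]], expr)
        save("epicentre_expression_comparison", comp)

    manifest = {
        "config_hash": cfg_hash,
        "artifacts": {k: {"path": str(v.relative_to(out)), "sha256": _sha256(v)}
                      for k, v in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def report(run_dir: str | Path) -> pd.DataFrame:
    """One-row-per-analysis summary of a completed run; no recomputation."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError("incomplete run: manifest.json missing")
    manifest = json.loads(manifest_path.read_text())
    rows = []
    for name, meta in manifest["artifacts"].items():
        path = run_dir / meta["path"]
        status = "ok"
        if not path.exists():
            status = "absent"
        elif _sha256(path) != meta["sha256"]:
            status = "integrity-warning"
        rows.append({"analysis": name, "file": meta["path"], "status": status})
    return pd.DataFrame(rows).set_index("analysis")
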