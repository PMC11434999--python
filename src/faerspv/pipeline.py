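"""End-to-end pipeline: ingest -> screen -> demographics -> classes -> profiles.

Runs the whole analysis on either real FAERS-dialect files or a bundled
synthetic database, writing every stage's tabular output plus a manifest
(configuration echo, stage row counts, package version, seed) that makes
the run exactly reproducible.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .class_analysis import all_class_associations, class_signal_fraction, write_class_tables
from .demographics import dichotomize, stratum_association, write_demographic_csv
from .disproportionality import (
    SignalCriteria,
    results_to_frame,
    screen_all_drugs,
    signal_drugs,
    write_volcano_csv,
)
from .errors import ConfigError
from .faers_model import (
    build_table_a,
    build_table_b,
    count_tsd_reports,
    deduplicate,
    read_faers_table,
)
from .multivariate import (
    DEFAULT_PT_MIN_REPORTS,
    build_lnror_matrix,
    interpret_components,
    pca,
    regress_pc1_on_lnror,
    ward_cluster,
)
from .synthetic import SyntheticConfig, generate, scaled_pt_floor
from .vocab import AtcClassMap, TASTE_SMELL_SMQ


@dataclass
class PipelineConfig:
    """Everything one run needs.

    Provide either the three input file paths (plus an ATC map CSV) or a
    :class:`SyntheticConfig`; thresholds default to the published
    screening rules (p < 0.05, ROR > 1, >= 100 reports; age cutoff 70;
    PT floor 3000 at full FAERS scale, rescaled automatically for
    synthetic runs; 3 clusters).
    """

    out_dir: Path
    demo_path: Path | None = None
    drug_path: Path | None = None
    reac_path: Path | None = None
    atc_map_path: Path | None = None
    synthetic: SyntheticConfig | None = None
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    age_cutoff: float = 70.0
    pt_min_reports: int | None = None
    k_clusters: int = 3
    seed: int = 0

    def validate(self) -> None:
        file_mode = all(p is not None for p in (self.demo_path, self.drug_path, self.reac_path))
        if self.synthetic is None and not file_mode:
            raise ConfigError("provide demo/drug/reac paths or a synthetic config")
        if self.synthetic is None and self.atc_map_path is None:
            raise ConfigError("file-based runs need an ATC map CSV")
        if self.k_clusters < 1:
            raise ConfigError("k_clusters must be >= 1")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }
    smq = TASTE_SMELL_SMQ

    def stage(name: str, **info) -> None:
        manifest["stages"][name] = {**info, "elapsed_s": round(time.time() - t0, 3)}

    # -- ingest ------------------------------------------------------------
    t0 = time.time()
    if config.synthetic is not None:
        dataset = generate(config.synthetic)
        input_dir = out / "input"
        dataset.write(input_dir)
        demo_path, drug_path, reac_path = (
            input_dir / "DEMO.txt", input_dir / "DRUG.txt", input_dir / "REAC.txt",
        )
        atc_map = AtcClassMap(config.synthetic.atc_mapping())
        smq = config.synthetic.smq
        pt_floor = (
            config.pt_min_reports
            if config.pt_min_reports is not None
            else scaled_pt_floor(config.synthetic.n_reports)
        )
        manifest["synthetic"] = True
    else:
        demo_path, drug_path, reac_path = config.demo_path, config.drug_path, config.reac_path
        atc_map = AtcClassMap.from_csv(config.atc_map_path)
        pt_floor = (
            config.pt_min_reports
            if config.pt_min_reports is not None
            else DEFAULT_PT_MIN_REPORTS
        )
        manifest["synthetic"] = False

    demo = deduplicate(read_faers_table(demo_path, "DEMO"), "DEMO")
    drug = deduplicate(read_faers_table(drug_path, "DRUG"), "DRUG")
    reac = deduplicate(read_faers_table(reac_path, "REAC"), "REAC")
    table_a = build_table_a(demo, drug, reac, smq)
    table_a.to_csv(out / "table_a.csv")
    manifest["outputs"].append("table_a.csv")
    stage("ingest", demo_rows=len(demo), drug_rows=len(drug), reac_rows=len(reac),
          table_a_reports=table_a.n_reports)

    l01 = atc_map.drugs

    # -- report counts -----------------------------------------------------
    t0 = time.time()
    counts = count_tsd_reports(table_a, l01)
    counts.to_json(out / "tsd_counts.json")
    manifest["outputs"].append("tsd_counts.json")
    stage("counts", n_tsd_any=counts.n_tsd_any)

    # -- per-drug screening ------------------------------------------------
    t0 = time.time()
    results = screen_all_drugs(table_a, smq.all_terms, criteria=config.criteria)
    write_volcano_csv(results, out / "volcano.csv")
    manifest["outputs"].append("volcano.csv")
    signals = sorted(set(signal_drugs(results)) & l01)
    stage("screen", n_drugs=len(results), n_signal_antineoplastics=len(signals))

    # -- demographics ------------------------------------------------------
    t0 = time.time()
    table_b = build_table_b(demo, drug, reac, l01, smq)
    table_b.to_csv(out / "table_b.csv", index=False)
    splits = [
        dichotomize(table_b, "age", config.age_cutoff),
        dichotomize(table_b, "gender"),
    ]
    write_demographic_csv(splits, out / "demographics.csv")
    manifest["outputs"] += ["table_b.csv", "demographics.csv"]
    age_res = stratum_association(splits[0])
    stage("demographics", table_b_rows=len(table_b),
          age_ror=round(age_res.ror, 4))

    # -- class analysis ----------------------------------------------------
    t0 = time.time()
    fraction = class_signal_fraction(signals, atc_map)
    class_results = all_class_associations(table_a, smq.all_terms, atc_map,
                                           config.criteria)
    write_class_tables(fraction, class_results,
                       out / "class_signal_fraction.csv",
                       out / "class_associations.csv")
    manifest["outputs"] += ["class_signal_fraction.csv", "class_associations.csv"]
    stage("classes", n_classes=len(class_results))

    # -- multivariate profiling --------------------------------------------
    t0 = time.time()
    if len(signals) >= 3:
        matrix = build_lnror_matrix(table_a, signals, smq, pt_floor)
        matrix.to_csv(out / "lnror_matrix.csv")
        clustering = ward_cluster(matrix, config.k_clusters)
        clustering.assignment_frame().to_csv(out / "clusters.csv", index=False)
        (out / "dendrogram.nwk").write_text(clustering.to_newick() + "\n")
        comp = pca(matrix)
        comp.loadings.to_csv(out / "pca_loadings.csv")
        comp.scores.to_csv(out / "pca_scores.csv")
        interpret_components(comp, matrix).to_csv(
            out / "pca_interpretation.csv", index=False
        )
        overall = pd.Series(
            {r.entity: r.ln_ror for r in results if r.entity in set(signals)}
        )
        fit = regress_pc1_on_lnror(comp, overall)
        (out / "pc1_regression.json").write_text(json.dumps({
            "slope": fit.slope, "intercept": fit.intercept,
            "r_squared": fit.r_squared, "p_value": fit.p_value,
        }, indent=2))
        manifest["outputs"] += [
            "lnror_matrix.csv", "clusters.csv", "dendrogram.nwk",
            "pca_loadings.csv", "pca_scores.csv", "pca_interpretation.csv",
            "pc1_regression.json",
        ]
        stage("profile", n_signal_drugs=len(matrix.drugs), n_pts=len(matrix.pts),
              pt_floor=pt_floor,
              explained_fraction=[round(float(f), 4) for f in comp.explained_fraction])
    else:
        stage("profile", skipped=f"only {len(signals)} signal drugs (need >= 3)")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
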