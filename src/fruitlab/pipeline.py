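"""End-to-end orchestration of the colour-characterization analysis.

One ``run_pipeline`` call reproduces the full study workflow on a panel:
replicate aggregation → threshold classification at harvest → purple
K-means subclassification (K ∈ {2, 3, 4}) with agreement against the
threshold labels → ripeness cluster-number selection and K = 3
yellow/ochre/brown mapping → stage-transition deltas → trait
correlations → Evanno ΔK (when run summaries are supplied) → surrogate-Q
association scan → per-category CIELAB ranges and gradient swatches.

Every stage's table is written as CSV under the output directory, each
run is reproducible byte-for-byte from the same inputs, config and seed,
and no accession is dropped silently: every exclusion is logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import classify as cl
from . import io as fio
from .colorimetry import chroma, hue, rgb_hex, stage_deltas
from .genetics import association_scan, evanno_delta_k, surrogate_q
from .panel import PanelConfig, generate_panel
from .traits import build_trait_matrix, pearson_matrix

logger = logging.getLogger("fruitlab")

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "render_gradient_blocks"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults mirror the reference analysis."""

    measurements: str | None = None
    dus: str | None = None
    genotypes: str | None = None
    structure_runs: str | None = None
    q_matrix: str | None = None
    synthetic: bool = False
    panel: PanelConfig = field(default_factory=PanelConfig)
    l_white: float = 70.0
    a_green: float = -5.0
    b_violet: float = -2.5
    margin: float = 2.0
    alpha_corr: float = 0.05
    alpha_assoc: float = 0.001
    n_subpopulations: int = 2
    purple_k_candidates: tuple[int, ...] = (2, 3, 4)
    ripeness_k_range: tuple[int, int] = (2, 8)
    seed: int = 0
    out_dir: str = "fruitlab_out"

    def __post_init__(self) -> None:
        if not 0 < self.alpha_corr < 1 or not 0 < self.alpha_assoc < 1:
            raise ValueError("alpha levels must lie in (0, 1)")
        for name in ("l_white", "a_green", "b_violet", "margin"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All tables one pipeline run produces, plus the config hash."""

    classification: pd.DataFrame
    deltas: pd.DataFrame
    correlation_r: pd.DataFrame
    correlation_p: pd.DataFrame
    purple_clusters: pd.DataFrame
    purple_agreement: pd.DataFrame
    ripeness_diag: pd.DataFrame
    ripeness_labels: pd.DataFrame
    delta_k: pd.DataFrame | None
    optimal_k: int | None
    associations: pd.DataFrame | None
    category_ranges: pd.DataFrame
    config_hash: str


def _accession_means(measurements: pd.DataFrame) -> pd.DataFrame:
    return measurements.groupby(["accession", "stage"])[["L", "a", "b"]].mean()


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis and write all stage outputs to disk."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    logger.info("run config hash %s, seed %d", chash, cfg.seed)

    if cfg.synthetic:
        panel = generate_panel(cfg.panel, seed=cfg.seed)
        measurements, dus, genotypes = panel.measurements, panel.dus, panel.genotypes
        logger.info("synthetic panel: %d accessions", cfg.panel.n_accessions)
    else:
        if cfg.measurements is None or cfg.dus is None:
            raise ValueError("measurements and DUS paths are required unless synthetic=True")
        measurements = fio.read_measurements(cfg.measurements)
        dus = fio.read_dus(cfg.dus)
        genotypes = fio.read_genotypes(cfg.genotypes) if cfg.genotypes else None

    ids = sorted(measurements["accession"].unique())
    missing_dus = sorted(set(ids) - set(dus["accession"]))
    if missing_dus:
        logger.warning("accessions without DUS notes: %s", missing_dus)

    means = _accession_means(measurements)
    h = means.xs("H", level="stage").reindex(ids)
    p = means.xs("P", level="stage").reindex(ids)

    # --- harvest-maturity threshold classification --------------------
    clf = cl.HarvestColorClassifier(cfg.l_white, cfg.a_green, cfg.b_violet, cfg.margin)
    clf.fit(np.zeros((1, 3)))
    pulp = dus.set_index("accession")["FPC"].reindex(ids).eq(2) if "FPC" in dus.columns else None
    classification = clf.predict_frame(h.to_numpy(), None if pulp is None else pulp.to_numpy())
    classification.insert(0, "accession", ids)
    for i, row in classification.iterrows():
        if row.borderline:
            logger.warning("borderline classification %s: %s", row.accession, row.borderline)

    # --- stage-transition deltas --------------------------------------
    rows = []
    for a_id in ids:
        hv, pv = h.loc[a_id], p.loc[a_id]
        if hv.isna().any() or pv.isna().any():
            logger.warning("accession %s missing a stage; excluded from temporal analysis", a_id)
            continue
        d = stage_deltas(tuple(hv), tuple(pv))
        rows.append((a_id, chroma(tuple(hv)), hue(tuple(hv)), d.dL, d.da, d.db, d.dE, d.dC, d.dH))
    deltas = pd.DataFrame(rows, columns=["accession", "H_C", "H_H", "dL", "da", "db", "dE", "dC", "dH"])

    # --- purple subclassification (K-means vs thresholds) -------------
    purple_ids = classification.loc[classification.category == "purple", "accession"]
    hp = h.loc[purple_ids]
    purple_rows, agree_rows = [], []
    for k in cfg.purple_k_candidates:
        if len(hp) <= k:
            logger.warning("too few purple accessions for K=%d; skipped", k)
            continue
        m = cl.kmeans_fit(hp.to_numpy(), k, seed=cfg.seed)
        if k == 2:
            m.map_purple_intensity()
        labels = m.descriptor_labels() if m.descriptor_map_ else m.labels_.astype(str)
        for a_id, lab in zip(purple_ids, labels):
            purple_rows.append((a_id, k, lab))
        sub = classification.set_index("accession").loc[purple_ids, "subtype"]
        _, ari = cl.agreement(labels, sub.to_numpy())
        agree_rows.append((k, m.wcss_, m.silhouette_, ari))
    purple_clusters = pd.DataFrame(purple_rows, columns=["accession", "K", "cluster"])
    purple_agreement = pd.DataFrame(agree_rows, columns=["K", "wcss", "silhouette", "ari_vs_subtype"])

    # --- ripeness clustering ------------------------------------------
    sel = cl.select_k(p.to_numpy(), range(cfg.ripeness_k_range[0], cfg.ripeness_k_range[1] + 1),
                      seed=cfg.seed)
    m3 = cl.kmeans_fit(p.to_numpy(), 3, seed=cfg.seed).map_ripeness()
    ripeness_labels = pd.DataFrame(
        {"accession": ids, "cluster": m3.labels_, "category": m3.descriptor_labels()}
    )
    logger.info("ripeness: elbow K=%s, silhouette K=%s", sel.elbow_k, sel.silhouette_k)

    # --- trait correlations -------------------------------------------
    tm = build_trait_matrix(measurements, dus)
    corr = pearson_matrix(tm, alpha=cfg.alpha_corr)

    # --- population structure and association -------------------------
    delta_k_table, optimal_k, assoc = None, None, None
    if cfg.structure_runs:
        delta_k_table, optimal_k = evanno_delta_k(fio.read_structure_runs(cfg.structure_runs))
        logger.info("Evanno optimal K = %d", optimal_k)
    if genotypes is not None:
        q = (fio.read_q_matrix(cfg.q_matrix) if cfg.q_matrix
             else surrogate_q(genotypes, cfg.n_subpopulations, seed=cfg.seed))
        assoc = association_scan(tm, genotypes, q, alpha=cfg.alpha_assoc)
        logger.info("association scan: %d significant cells at p<%g",
                    int(assoc["significant"].sum()), cfg.alpha_assoc)
    else:
        logger.warning("no genotype table; association stage skipped")

    # --- category ranges and gradient blocks --------------------------
    range_in = pd.concat(
        [
            h.assign(label=classification.set_index("accession")["label"].reindex(h.index)),
            p.assign(label=("ripe-" + ripeness_labels.set_index("accession")["category"]).reindex(p.index)),
        ]
    )
    ranges = cl.derive_category_ranges(range_in.reset_index(drop=True))
    range_table = pd.DataFrame(
        [
            {
                "label": r.label, "n": r.n,
                "L_min": r.lab_min[0], "L_max": r.lab_max[0],
                "a_min": r.lab_min[1], "a_max": r.lab_max[1],
                "b_min": r.lab_min[2], "b_max": r.lab_max[2],
                "hex_codes": " ".join(r.hex_codes),
            }
            for r in ranges
        ]
    )
    render_gradient_blocks(ranges, out / "gradients")

    bundle = ReportBundle(
        classification, deltas, corr.r, corr.p, purple_clusters, purple_agreement,
        sel.diagnostics, ripeness_labels, delta_k_table, optimal_k, assoc, range_table, chash,
    )
    _write_bundle(bundle, out)
    return bundle


def _write_bundle(b: ReportBundle, out: Path) -> None:
    fmt = "%.6g"
    named = {
        "classification": b.classification,
        "stage_deltas": b.deltas,
        "correlation_r": b.correlation_r,
        "correlation_p": b.correlation_p,
        "purple_clusters": b.purple_clusters,
        "purple_agreement": b.purple_agreement,
        "ripeness_diagnostics": b.ripeness_diag,
        "ripeness_labels": b.ripeness_labels,
        "category_ranges": b.category_ranges,
    }
    if b.delta_k is not None:
        named["delta_k"] = b.delta_k
    if b.associations is not None:
        named["associations"] = b.associations
    for name, df in named.items():
        keep_index = name.startswith("correlation")
        df.to_csv(out / f"{name}.csv", index=keep_index, float_format=fmt)
    (out / "run_info.json").write_text(
        json.dumps({"config_hash": b.config_hash, "optimal_k": b.optimal_k}, indent=2)
    )


def render_gradient_blocks(ranges, out_dir, swatch: int = 60, label_height: int = 14):
    """One horizontal gradient strip per category, hex codes annotated.

    Deterministic pixel output for a fixed input; returns written paths.
    """
    if not ranges:
        raise ValueError("no category ranges to render")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for r in ranges:
        n = len(r.gradient)
        img = Image.new("RGB", (swatch * n, swatch + label_height), "white")
        draw = ImageDraw.Draw(img)
        for i, c in enumerate(r.gradient):
            draw.rectangle([i * swatch, 0, (i + 1) * swatch - 1, swatch - 1], fill=(c.r, c.g, c.b))
            draw.text((i * swatch + 2, swatch + 1), rgb_hex(c), fill="black")
        path = out_dir / f"{r.label.replace('/', '-')}.png"
        img.save(path)
        paths.append(path)
    return paths
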