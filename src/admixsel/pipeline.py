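"""End-to-end workflows with reproducible run manifests.

Two pipelines mirror how the statistics are meant to be chained:

* scan: per-variant LRT -> calibration (genomic control or gamma fit) ->
  Benjamini-Hochberg FDR -> LD-companion filter -> genome-wide
  significance flags.
* power: synthetic region -> coupled Wright-Fisher grid -> the same scan
  and calibration per cell.

Every run emits a JSON manifest (command, config, seeds, input digests,
library versions, timestamps) so outputs are a pure function of
(inputs, config, seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .popdata import AdmixtureMatrix, VariantRecord, ValidationError
from .scan import (
    GENOME_WIDE_ALPHA,
    bh_qvalues,
    calibrate,
    ld_companion_filter,
    lrt_batch,
)
from .wfsim import PowerRegion, power_grid

logger = logging.getLogger(__name__)

__all__ = ["ScanPipelineConfig", "run_scan_pipeline", "run_power_pipeline", "build_manifest"]


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def build_manifest(command: str, config: dict, seeds: dict, inputs: Sequence) -> dict:
    """Assemble the reproducibility manifest for one run."""
    import scipy

    return {
        "command": command,
        "config": config,
        "seeds": seeds,
        "inputs": {str(p): _digest(p) for p in inputs},
        "versions": {
            "admixsel": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


@dataclass(frozen=True)
class ScanPipelineConfig:
    calibration: str = "genomic_control"  # or "gamma_fit"
    fdr_q: float = 0.1
    ld_window: int = 200_000
    min_companions: int = 1
    r2_min: float = 0.5
    sig_threshold: float = GENOME_WIDE_ALPHA


def run_scan_pipeline(
    records: Sequence[VariantRecord],
    M: AdmixtureMatrix,
    config: ScanPipelineConfig = ScanPipelineConfig(),
    ld: Optional[pd.DataFrame] = None,
    out: Optional[Path] = None,
    manifest_inputs: Sequence = (),
):
    """Scan -> calibrate -> FDR -> LD filter -> significance flags.

    Returns ``(DataFrame, CalibrationReport, manifest)``.  When ``ld`` is
    None the companion filter is skipped and ``pass_filter`` mirrors the
    FDR column alone.
    """
    if not records:
        raise ValidationError("no variants to scan")
    npop = records[0].counts.n_populations
    if npop != M.n_populations:
        raise ValidationError(
            f"counts table has {npop} populations but admixture matrix has "
            f"{M.n_populations} rows"
        )
    X = np.array([r.counts.x for r in records])
    Ns = np.array([r.counts.N for r in records])
    logger.info("scan: %d variants, %d populations, k=%d sources", len(records), npop, M.k)
    stats, ell1, ell0, qhat = lrt_batch(X, Ns, M)
    df_dof = M.n_populations - M.k
    report, p_adj = calibrate(stats, df_dof, method=config.calibration)
    logger.info("calibration (%s): lambda_gc = %.4f", report.method, report.lambda_gc)

    from scipy import stats as sps

    table = pd.DataFrame(
        {
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "id": [r.variant_id for r in records],
            "stat": stats,
            "df": df_dof,
            "p_raw": sps.chi2.sf(stats, df_dof),
            "p_adj": p_adj,
        }
    )
    for j in range(M.k):
        table[f"q_hat_{j + 1}"] = qhat[:, j]
    table["q_value"] = bh_qvalues(table["p_adj"].to_numpy())
    n_fdr = int((table["q_value"] < config.fdr_q).sum())
    logger.info("FDR < %g: %d variants", config.fdr_q, n_fdr)
    if ld is not None:
        table = ld_companion_filter(
            table,
            ld,
            fdr_q=config.fdr_q,
            window=config.ld_window,
            min_companions=config.min_companions,
            r2_min=config.r2_min,
        )
    else:
        table["n_companions"] = -1
        table["pass_filter"] = table["q_value"] < config.fdr_q
        logger.info("LD-companion filter skipped (no LD table)")
    table["significant"] = table["p_adj"] < config.sig_threshold
    logger.info(
        "genome-wide significant at %g: %d variants",
        config.sig_threshold,
        int(table["significant"].sum()),
    )
    manifest = build_manifest(
        command="scan",
        config=asdict(config),
        seeds={},
        inputs=manifest_inputs,
    )
    manifest["lambda_gc"] = report.lambda_gc
    if out is not None:
        out = Path(out)
        table.to_csv(out, sep="\t", index=False, float_format="%.10g")
        with open(out.with_suffix(".manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return table, report, manifest


@dataclass(frozen=True)
class PowerPipelineConfig:
    s_values: tuple = (0.0, 0.005, 0.01, 0.02, 0.05, 0.1)
    generation_values: tuple = (0, 10, 20, 50, 100)
    n_variants: int = 1000
    maf_min: float = 0.05
    n_null: int = 5000
    seed: int = 0


def run_power_pipeline(
    region: PowerRegion,
    config: PowerPipelineConfig = PowerPipelineConfig(),
    out: Optional[Path] = None,
    manifest_inputs: Sequence = (),
):
    """Run the full power grid and emit the long-format table + manifest."""
    table = power_grid(
        region,
        config.s_values,
        config.generation_values,
        n_variants=config.n_variants,
        maf_min=config.maf_min,
        seed=config.seed,
        n_null=config.n_null,
    )
    manifest = build_manifest(
        command="power",
        config={
            **asdict(config),
            "Ne": region.Ne,
            "focal": region.focal,
            "sample_sizes": [int(v) for v in region.sample_sizes],
        },
        seeds={"seed": config.seed},
        inputs=manifest_inputs,
    )
    if out is not None:
        out = Path(out)
        table.to_csv(out, sep="\t", index=False, float_format="%.10g")
        with open(out.with_suffix(".manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return table, manifest
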