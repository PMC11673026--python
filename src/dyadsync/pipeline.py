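"""End-to-end orchestration: recordings -> FAA -> bins -> concordance -> models."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .io import RawRecording, ClusterSpec, DEFAULT_CLUSTERS
from .preprocess import preprocess_recording
from .spectral import faa_for_recording
from .synchrony import bin_faa, dyad_ccc, group_ccc, aggregate_ccc

logger = logging.getLogger("dyadsync")

__all__ = ["run_pipeline", "PipelineResult"]


class PipelineResult(dict):
    """Bundle of tidy tables keyed by name (dict subclass for convenience)."""

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, obj in self.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(outdir / f"{name}.csv", index=False)


def run_pipeline(
    dyads: dict[str, tuple[RawRecording, RawRecording]],
    config: PipelineConfig | None = None,
    clusters: ClusterSpec = DEFAULT_CLUSTERS,
) -> PipelineResult:
    """Process ≥1 dyad of raw recordings through the full analysis.

    ``dyads`` maps dyad_id -> (partner 1, partner 2).  Conditions present
    for only one partner are skipped for that dyad with a logged warning.
    Returns tables: ``qc``, ``faa_epochs``, ``faa_bins``, ``ccc_subject``,
    ``ccc_group``, ``ccc_per_dyad_mean``, ``ccc_descriptives``.
    """
    if not dyads:
        raise ValueError("need at least one dyad")
    config = config or PipelineConfig()

    qc_rows, faa_frames, bin_frames = [], [], []
    subject_ccc_frames = []
    all_bins: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}

    for dyad_id, (rec1, rec2) in dyads.items():
        pair_bins = []
        for rec in (rec1, rec2):
            clean, qc = preprocess_recording(rec, config, logger=logger)
            qc_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "dyad_id": dyad_id,
                    "n_bad_channels": len(qc["bad_channels"]),
                    "bad_channels": ";".join(qc["bad_channels"]),
                    "reference_check": qc["reference_check_max_abs_mean"],
                    **{
                        f"pct_rejected[{k}]": v
                        for k, v in qc["pct_samples_rejected"].items()
                    },
                }
            )
            faa = faa_for_recording(clean, config, clusters, logger=logger)
            faa_frames.append(faa)
            bins = bin_faa(faa, bin_epochs=config.bin_epochs)
            bin_frames.append(bins)
            pair_bins.append(bins)

        b1, b2 = pair_bins
        shared = set(b1["condition"]) & set(b2["condition"])
        for b, other in ((b1, b2), (b2, b1)):
            only = set(b["condition"]) - shared
            for cond in only:
                logger.warning(
                    "dyad %s: condition %r present for only one partner; skipped",
                    dyad_id, cond,
                )
        b1 = b1[b1["condition"].isin(shared)]
        b2 = b2[b2["condition"].isin(shared)]
        all_bins[dyad_id] = (b1, b2)
        subject_ccc_frames.append(
            dyad_ccc(b1, b2, lags=config.lags_bins, ddof=config.ccc_ddof)
        )

    ccc_subject = pd.concat(subject_ccc_frames, ignore_index=True)
    ccc_grp = group_ccc(all_bins, lags=config.lags_bins, ddof=config.ccc_ddof)
    summaries = aggregate_ccc(ccc_subject)
    return PipelineResult(
        qc=pd.DataFrame(qc_rows),
        faa_epochs=pd.concat(faa_frames, ignore_index=True),
        faa_bins=pd.concat(bin_frames, ignore_index=True),
        ccc_subject=ccc_subject,
        ccc_group=ccc_grp,
        ccc_per_dyad_mean=summaries["per_dyad_mean"],
        ccc_descriptives=summaries["descriptives"],
    )
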