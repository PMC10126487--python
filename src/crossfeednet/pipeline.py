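"""End-to-end pipeline: simulate/load -> abruptness -> coupling runs ->
per-day networks -> hierarchy metrics -> centrality -> keystone tables.

All tabular outputs are TSV, nested reports are JSON, and every run
writes a machine-readable manifest naming the configuration hash and the
seeds used, so reruns with the same configuration are bit-identical.
Structured progress goes to the module logger (stderr when the CLI
configures it); result data only ever goes to files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .centrality import centrality_report, keystone_ranking
from .exchange import (
    CommunityModel,
    metabolic_interaction_potential,
    metabolic_resource_overlap,
    metabolite_frequencies,
    replicate_runs,
    standardize_frequencies,
    transfer_attribution,
)
from .hierarchy import hierarchy_report
from .network import build_network, detect_nodes
from .synthetic import ExchangeSpec, TimeSeriesSpec, simulate_exchange_community, simulate_timeseries
from .timeseries import AbundanceSeries, abruptness

logger = logging.getLogger("crossfeednet")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "DEFAULT_NETWORK_DAYS"]

#: default sampling schedule for per-day networks: 13 time points across
#: a 110-day series (days 1, 10, 20, 24, 30, 40, ..., 110)
DEFAULT_NETWORK_DAYS = [1, 10, 20, 24, 30, 40, 50, 60, 70, 80, 90, 100, 110]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Tunable parameters of the full analysis."""

    window_w: int = 5
    edge_threshold: float = 0.0
    n_runs: int = 10
    base_seed: int = 1
    mode: str = "auto"  # exhaustive | montecarlo | auto
    n_samples: int = 1000
    detection_threshold: float = 0.0
    damping: float = 0.85
    mro_denominator: str = "min"
    exhaustive_limit: int = 12
    mip_exact_limit: int = 20
    network_days: Optional[list[int]] = None  # None = the default 13-day schedule
    top_k: int = 5

    def validate(self) -> None:
        if self.window_w < 1:
            raise ValueError("window_w must be >= 1")
        if not 0.0 <= self.edge_threshold <= 1.0:
            raise ValueError("edge_threshold must lie in [0, 1]")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.mode not in ("auto", "exhaustive", "montecarlo"):
            raise ValueError("mode must be auto, exhaustive or montecarlo")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must lie in (0, 1)")
        if self.mro_denominator not in ("min", "union", "mean"):
            raise ValueError("mro_denominator must be min, union or mean")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage errors must carry the stage name
                raise PipelineError(f"stage {name}: {exc}") from exc
        return inner
    return wrap


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    ts_spec: Optional[TimeSeriesSpec] = None,
    ex_spec: Optional[ExchangeSpec] = None,
    abundance_path=None,
    community_path=None,
) -> dict:
    """Run the full analysis and write all outputs under ``out_dir``.

    Inputs are either file paths (abundance TSV + community JSON) or
    synthetic specs; when neither is given for a stage, the default
    synthetic spec with the configured base seed is used.  Species ids in
    the abundance table and the community model must overlap for per-day
    networks to be meaningful.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    manifest: dict = {
        "package": "crossfeednet",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": chash,
        "seeds": [config.base_seed + i for i in range(config.n_runs)],
        "outputs": [],
        "skipped": [],
    }

    def _write(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["outputs"].append(name)
        return path

    # --- abundance series -------------------------------------------------
    @_stage("abundance")
    def load_series() -> AbundanceSeries:
        if abundance_path is not None:
            return AbundanceSeries.from_tsv(abundance_path)
        spec = ts_spec or TimeSeriesSpec(seed=config.base_seed)
        logger.info("stage=abundance simulating spec seed=%d", spec.seed)
        series = simulate_timeseries(spec)
        _write("abundance.tsv", series.to_tsv)
        return series

    series = load_series()

    # --- abruptness -------------------------------------------------------
    @_stage("abruptness")
    def run_abruptness():
        result = abruptness(series, w=config.window_w)
        _write("abruptness.tsv", result.to_tsv)
        logger.info("stage=abruptness peak day=%d value=%.3f", result.argmax_day, result.a.max())
        return result

    run_abruptness()

    # --- community model + coupling runs ----------------------------------
    @_stage("exchange")
    def load_model() -> CommunityModel:
        if community_path is not None:
            return CommunityModel.from_json(community_path)
        spec = ex_spec or ExchangeSpec(
            n_species=min(series.n_species, config.exhaustive_limit),
            loop_count=2,
            seed=config.base_seed,
        )
        logger.info("stage=exchange simulating community seed=%d", spec.seed)
        model = simulate_exchange_community(spec)
        _write("community.json", model.to_json)
        return model

    model = load_model()

    @_stage("exchange")
    def run_exchange():
        rep = replicate_runs(
            model,
            n_runs=config.n_runs,
            base_seed=config.base_seed,
            mode=config.mode,
            n_samples=config.n_samples,
            exhaustive_limit=config.exhaustive_limit,
            mro_denominator=config.mro_denominator,
            mip_exact_limit=config.mip_exact_limit,
        )
        for run in rep.runs:
            frame = run.to_long()
            _write(
                f"scs_run_{run.run_seed}.tsv",
                lambda p, f=frame: f.to_csv(p, sep="\t", index=False),
            )
        _write("scs_aggregate.tsv", lambda p: rep.to_long().to_csv(p, sep="\t", index=False))
        return rep

    rep = run_exchange()

    # --- per-day networks, hierarchy, centrality, transfers, scores -------
    available_days = set(int(d) for d in series.day_labels)
    days = config.network_days or [d for d in DEFAULT_NETWORK_DAYS if d in available_days]
    if not days:
        days = sorted(available_days)

    hierarchy_rows, centrality_records, transfer_rows, score_rows = [], [], [], []
    community_species = set(model.species_ids)
    (out / "networks").mkdir(exist_ok=True)

    for day in days:
        @_stage(f"network day={day}")
        def per_day(day=day):
            detected = detect_nodes(series, day, config.detection_threshold)
            detected &= community_species
            net = build_network(
                rep.runs, threshold=config.edge_threshold, detected=detected, day=day
            )
            _write(f"networks/day_{day}.tsv", net.to_tsv)
            # transfers within the detected sub-community, standardized per day
            if detected:
                transfers = transfer_attribution(model, detected)
                freq = metabolite_frequencies(transfers)
                std = standardize_frequencies(freq)
                for met in freq.index:
                    transfer_rows.append(
                        {"day": day, "metabolite": met, "count": int(freq[met]),
                         "standardized": float(std[met])}
                    )
            # community-scale scores on the detected sub-community
            if len(detected) >= 2:
                sub = model.subset(detected)
                mip = metabolic_interaction_potential(sub, exact_limit=config.mip_exact_limit)
                mro = metabolic_resource_overlap(sub, denominator=config.mro_denominator)
                score_rows.append(
                    {"day": day, "mip": mip.mip, "mip_exact": mip.exact, "mro": mro,
                     "n_detected": len(detected)}
                )
            if len(detected) < 2:
                logger.info("stage=network day=%d insufficient nodes (%d)", day, len(detected))
                manifest["skipped"].append(
                    {"day": day, "stage": "hierarchy/centrality",
                     "reason": "insufficient nodes", "n_detected": len(detected)}
                )
                return
            hrep = hierarchy_report(net)
            hierarchy_rows.append({"day": day, **{k: v for k, v in hrep.to_dict().items() if k != "f_values"}})
            for run in rep.runs:
                run_net = build_network(
                    [run], threshold=config.edge_threshold, detected=detected, day=day
                )
                crep = centrality_report(run_net, damping=config.damping, day=day)
                frame = crep.to_frame()
                frame["run"] = run.run_seed
                centrality_records.append(frame)

        per_day()

    @_stage("reports")
    def write_reports():
        if hierarchy_rows:
            _write("hierarchy.tsv", lambda p: pd.DataFrame(hierarchy_rows).to_csv(p, sep="\t", index=False))
        if transfer_rows:
            _write("transfers.tsv", lambda p: pd.DataFrame(transfer_rows).to_csv(p, sep="\t", index=False))
        if score_rows:
            _write("community_scores.tsv", lambda p: pd.DataFrame(score_rows).to_csv(p, sep="\t", index=False))
        _write("community_scores.json", lambda p: Path(p).write_text(
            json.dumps(rep.scores.to_dict(), indent=1) + "\n"
        ))
        if centrality_records:
            records = pd.concat(centrality_records, ignore_index=True)
            tables = keystone_ranking(records, top_k=config.top_k)
            _write("centrality.tsv", lambda p: tables["per_day"].to_csv(p, sep="\t", index=False))
            _write("keystones.tsv", lambda p: tables["overall"].to_csv(p, sep="\t", index=False))

    write_reports()

    manifest["outputs"].sort()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
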