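"""End-to-end pipeline: simulate (or load) → filter → damage → sex → mito.

``run_pipeline`` takes a plain configuration mapping (typically loaded from
YAML), runs the stages, and returns a :class:`RunReport` that serialises
losslessly to JSON.  All thresholds in force are echoed into the report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .damage import DamageParams, NO_UDG, fit_damage_params, terminal_substitution_profile
from .genome import HG19_LENGTHS, normalize_chrom
from .mtdna import build_pileup, call_consensus, coverage_stats, estimate_contamination
from .read_processing import FilterConfig, count_by_chromosome, filter_reads, remove_duplicates
from .reads import parse_alignments
from .sexing import SexEstimate, SexThresholds, combined_verdict, sex_report
from .simulate import MT_NAME, SimConfig, simulate_reads, simulate_reference

log = logging.getLogger(__name__)


class _SexingSkipped(Exception):
    """Internal control flow: the sexing stage was disabled by config."""


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    provenance: dict
    filtering: dict
    damage: dict
    sexing: dict | None
    mtdna: dict | None

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _estimate_dict(est: SexEstimate | None) -> dict | None:
    if est is None:
        return None
    return {
        "method": est.method,
        "estimate": est.estimate,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "n_used": est.n_used,
        "call": est.call,
    }


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: Mapping[str, Any]) -> RunReport:
    """Run the configured stages and assemble the report.

    Config keys (all optional except one of ``simulate``/``input``):

    * ``seed`` — master seed for simulation and bootstrap.
    * ``simulate`` — SimConfig fields; when present the dataset is simulated.
    * ``input`` — {"alignments": path, "lengths": {chrom: bp} or path}.
    * ``filter`` — FilterConfig fields plus ``dedup`` (default True).
    * ``damage`` — {"threshold": 3.0, "max_offset": 25, "fit": True,
      "delta"/"phi"/"epsilon" when not fitting}.
    * ``sex`` — SexThresholds fields.
    * ``mtdna`` — {"enabled": bool, "min_depth": 5, "min_freq": 0.8,
      "bootstrap": 200, "panel": path or None}.
    """
    seed = int(config.get("seed", 0))
    panel: list[str] | None = None
    mito_ref_len: int | None = None

    # --- acquire reads -----------------------------------------------------
    try:
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"])
            sim_kwargs.setdefault("seed", seed)
            cfg = SimConfig(**sim_kwargs)
            ref = simulate_reference(cfg)
            reads, _truth = simulate_reads(cfg, ref)
            lengths = {normalize_chrom(k): v for k, v in ref.lengths.items()}
            panel = ref.contaminant_mt
            mito_ref_len = len(ref.chromosomes[MT_NAME])
            endo_mt = ref.chromosomes[MT_NAME]
        elif "input" in config:
            spec = config["input"]
            reads = parse_alignments(spec["alignments"])
            raw = spec.get("lengths", HG19_LENGTHS)
            if isinstance(raw, (str, Path)):
                import pandas as pd
                df = pd.read_csv(raw, sep="\t", dtype={"chrom": str})
                raw = dict(zip(df["chrom"], df["length"]))
            lengths = {normalize_chrom(k): int(v) for k, v in raw.items()}
            mito_ref_len = lengths.get("MT")
            endo_mt = None
            panel_path = config.get("mtdna", {}).get("panel")
            if panel_path:
                from Bio import SeqIO
                panel = [str(rec.seq).upper()
                         for rec in SeqIO.parse(panel_path, "fasta")]
        else:
            raise ValueError("config needs a 'simulate' or 'input' section")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("input", exc) from exc

    n_input = len(reads)

    # --- filter ------------------------------------------------------------
    try:
        fspec = dict(config.get("filter", {}))
        dedup = bool(fspec.pop("dedup", True))
        fcfg = FilterConfig(**fspec)
        kept, stats = filter_reads(reads, fcfg)
        n_after_filter = len(kept)
        if dedup:
            kept = remove_duplicates(kept)
        n_dups_removed = n_after_filter - len(kept)
    except Exception as exc:
        raise PipelineError("filter", exc) from exc

    filtering = {
        "n_input": n_input,
        "removed_mapq": stats.removed_mapq,
        "removed_short": stats.removed_short,
        "removed_long": stats.removed_long,
        "removed_duplicates": n_dups_removed,
        "n_retained": len(kept),
        "config": {"min_mapq": fcfg.min_mapq, "min_len": fcfg.min_len,
                   "max_len": fcfg.max_len, "dedup": dedup},
    }

    # --- damage ------------------------------------------------------------
    try:
        dspec = dict(config.get("damage", {}))
        threshold = float(dspec.get("threshold", 3.0))
        max_offset = int(dspec.get("max_offset", 25))
        profile = terminal_substitution_profile(kept, max_offset=max_offset)
        if dspec.get("fit", True):
            params = fit_damage_params(profile)
        else:
            params = DamageParams(delta=dspec.get("delta", NO_UDG.delta),
                                  phi=dspec.get("phi", NO_UDG.phi),
                                  epsilon=dspec.get("epsilon", NO_UDG.epsilon))
        freq5 = profile.five_prime.frequency
        damage_block = {
            "five_prime_ct_head": [None if f != f else float(f) for f in freq5[:5]],
            "fitted": {"delta": params.delta, "phi": params.phi,
                       "epsilon": params.epsilon, "residual": params.residual},
            "threshold": threshold,
            "n_profile_reads": profile.n_reads,
        }
    except Exception as exc:
        raise PipelineError("damage", exc) from exc

    # --- sexing ------------------------------------------------------------
    sexing = None
    sspec = dict(config.get("sex", {}))
    sex_enabled = bool(sspec.pop("enabled", True))
    try:
        sthr = SexThresholds(**sspec)
        if not sex_enabled:
            raise _SexingSkipped
        srep = sex_report(kept, lengths, params, thresholds=sthr,
                          pmd_threshold=threshold)
        sexing = {
            "all": {"ry": _estimate_dict(srep.all_ry),
                    "rx": _estimate_dict(srep.all_rx)},
            "damaged": {"ry": _estimate_dict(srep.damaged_ry),
                        "rx": _estimate_dict(srep.damaged_rx)},
            "n_reads": srep.n_reads,
            "n_damaged": srep.n_damaged,
            "combined_all": combined_verdict(srep.all_ry, srep.all_rx),
            "thresholds": dataclasses.asdict(sthr),
        }
    except _SexingSkipped:
        pass
    except Exception as exc:
        raise PipelineError("sexing", exc) from exc

    # --- mito --------------------------------------------------------------
    mspec = dict(config.get("mtdna", {}))
    mtdna_block = None
    if mspec.get("enabled", True) and mito_ref_len:
        try:
            mito_reads = [r for r in kept if normalize_chrom(r.chrom) == "MT"]
            if mito_reads:
                pileup = build_pileup(mito_reads, mito_ref_len, circular=True)
                cons = call_consensus(pileup,
                                      min_depth=int(mspec.get("min_depth", 5)),
                                      min_freq=float(mspec.get("min_freq", 0.8)))
                cov = coverage_stats(pileup)
                mtdna_block = {
                    "n_reads": len(mito_reads),
                    "coverage": {"min": cov.min_depth, "max": cov.max_depth,
                                 "mean": round(cov.mean_depth, 1)},
                    "consensus_n_uncalled": cons.n_uncalled,
                    "contamination": None,
                }
                if endo_mt is not None and panel is None:
                    panel = []
                if panel:
                    try:
                        contam = estimate_contamination(
                            mito_reads, cons.sequence, panel, params,
                            n_bootstrap=int(mspec.get("bootstrap", 200)),
                            seed=seed,
                        )
                        mtdna_block["contamination"] = {
                            "proportion": contam.proportion,
                            "ci_low": contam.ci_low,
                            "ci_high": contam.ci_high,
                            "n_informative": contam.n_informative,
                            "panel_size": contam.panel_size,
                        }
                    except ValueError as exc:
                        mtdna_block["contamination"] = {"error": str(exc)}
        except Exception as exc:
            raise PipelineError("mtdna", exc) from exc

    provenance = {
        "package": "adnasex",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
    }
    return RunReport(provenance=provenance, filtering=filtering,
                     damage=damage_block, sexing=sexing, mtdna=mtdna_block)
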