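"""Config-driven orchestration: simulate -> phenotype -> associate -> enrich.

One YAML config drives a full reproducible run; every stage writes its
artifacts under the output directory and a JSON manifest records seeds,
versions, input digests and the counts at every filter so a run can be
audited end to end.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association as assoc
from . import enrichment as enr
from . import io as sio
from . import phenotype as phen
from .simulate import SimulationConfig, simulate_study

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("somnoprot")

DEFAULTS = {
    "phenotyping": {
        "min_daily_tst": 120,
        "min_days": 90,
        "day_rule": "wake-date",
        "main_rule": "tst",
    },
    "association": {
        "outcomes": ["secondary", "daytime", "afternoon"],
        "lambda_rule": "cv-min",
        "quadratic": False,
        "q_threshold": 0.05,
    },
    "enrichment": {
        "p_max": 0.01,
        "min_count": 3,
        "min_ef": 1.5,
        "kappa_threshold": 0.3,
        "mode": "union",  # or "per-outcome"
    },
}

_KNOWN_TOP = {
    "seed",
    "out_dir",
    "log_level",
    "simulate",
    "inputs",
    "phenotyping",
    "association",
    "enrichment",
}


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    log_level: str = "INFO"
    simulate: SimulationConfig | None = None
    inputs: dict = field(default_factory=dict)
    phenotyping: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)

    def to_manifest_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "log_level": self.log_level,
            "inputs": {k: str(v) for k, v in self.inputs.items()},
            "phenotyping": self.phenotyping,
            "association": self.association,
            "enrichment": self.enrichment,
        }
        if self.simulate is not None:
            sim = asdict(self.simulate)
            sim["effect_sizes"] = (
                None
                if self.simulate.effect_sizes is None
                else list(self.simulate.effect_sizes)
            )
            d["simulate"] = sim
        return d


def validate_config(path) -> RunConfig:
    """Parse and validate a YAML run config, applying defaults.

    All problems are collected and reported at once.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    problems: list[str] = []
    unknown = sorted(set(raw) - _KNOWN_TOP)
    if unknown:
        problems.append(f"unknown top-level keys: {unknown}")
    if "out_dir" not in raw:
        problems.append("out_dir is required")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")

    sections = {}
    for name, defaults in DEFAULTS.items():
        sec = dict(defaults)
        user = raw.get(name) or {}
        bad = sorted(set(user) - set(defaults))
        if bad:
            problems.append(f"unknown keys in {name}: {bad}")
        sec.update({k: v for k, v in user.items() if k in defaults})
        sections[name] = sec
    if not 0 < sections["association"]["q_threshold"] < 1:
        problems.append(
            f"association.q_threshold must lie in (0, 1), got "
            f"{sections['association']['q_threshold']}"
        )
    bad_outcomes = [
        o
        for o in sections["association"]["outcomes"]
        if o not in assoc.OUTCOME_FIELDS
    ]
    if bad_outcomes:
        problems.append(f"unknown association outcomes {bad_outcomes}")
    if not 0 < sections["enrichment"]["p_max"] < 1:
        problems.append("enrichment.p_max must lie in (0, 1)")
    if sections["enrichment"]["mode"] not in ("union", "per-outcome"):
        problems.append("enrichment.mode must be 'union' or 'per-outcome'")

    sim_cfg = None
    if raw.get("simulate") is not None:
        try:
            sim_raw = dict(raw["simulate"])
            sim_raw.setdefault("seed", seed if isinstance(seed, int) else 0)
            sim_cfg = SimulationConfig(**sim_raw)
        except (TypeError, ValueError) as exc:
            problems.append(f"simulate section invalid: {exc}")

    inputs = {k: Path(v) for k, v in (raw.get("inputs") or {}).items()}
    if sim_cfg is None:
        for key in ("episodes", "npx", "covariates", "gmt"):
            if key not in inputs:
                problems.append(f"inputs.{key} required when not simulating")
            elif not inputs[key].exists():
                problems.append(f"inputs.{key} does not exist: {inputs[key]}")

    if problems:
        raise ValueError("invalid run config:\n  - " + "\n  - ".join(problems))
    return RunConfig(
        seed=seed,
        out_dir=Path(raw["out_dir"]),
        log_level=str(raw.get("log_level", "INFO")),
        simulate=sim_cfg,
        inputs=inputs,
        phenotyping=sections["phenotyping"],
        association=sections["association"],
        enrichment=sections["enrichment"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_volcano(results, path) -> None:
    df = pd.DataFrame(
        {
            "assay_id": [r.assay_id for r in results],
            "beta": [r.beta_sleep for r in results],
            "neg_log10_p": [-np.log10(max(r.p, 1e-300)) for r in results],
            "significant": [r.q < assoc.SIGNIFICANCE_Q for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _write_enrichment(terms, path) -> None:
    rows = [
        {
            "rank": i + 1,
            "term_id": t.term_id,
            "biological_process": t.term_name,
            "proteins": ",".join(t.overlap_genes),
            "k": t.k,
            "K": t.K,
            "p": t.p,
            "enrichment_factor": t.enrichment_factor,
            "passed": t.passed,
            "cluster_id": t.cluster_id if t.cluster_id is not None else "",
            "representative": t.representative,
        }
        for i, t in enumerate(terms)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages; returns (and writes) the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config.to_manifest_dict(),
        "stages": {},
        "artifacts": {},
    }

    stage = "simulate"
    try:
        if config.simulate is not None:
            log.info("stage=simulate n=%d days=%d", config.simulate.n_participants,
                     config.simulate.n_days)
            bundle = simulate_study(config.simulate)
            ep_path = out / "episodes.csv"
            sio.write_episode_log(bundle.episodes, ep_path)
            cov_path = out / "covariates.csv"
            sio.write_covariates(bundle.cohort, cov_path)
            npx_path = out / "npx_long.csv"
            sio.write_npx_long(bundle.npx_long, npx_path)
            gmt_path = out / "genesets.gmt"
            sio.write_gmt(bundle.genesets, gmt_path)
            truth_path = out / "ground_truth.json"
            with open(truth_path, "w") as fh:
                json.dump(
                    {
                        "signal_assay_ids": bundle.truth.signal_assay_ids,
                        "true_betas": bundle.truth.true_betas,
                        "true_participant_latent": bundle.truth.true_participant_latent,
                        "planted_terms": bundle.truth.planted_terms,
                    },
                    fh,
                    indent=1,
                )
            config.inputs = {
                "episodes": ep_path,
                "npx": npx_path,
                "covariates": cov_path,
                "gmt": gmt_path,
            }
            manifest["stages"]["simulate"] = {
                "n_participants": len(bundle.cohort),
                "n_episodes": len(bundle.episodes),
                "n_npx_records": int(len(bundle.npx_long)),
                "n_genesets": len(bundle.genesets),
                "n_signal_assays": len(bundle.truth.signal_assay_ids),
            }
        manifest["artifacts"]["inputs"] = {
            k: {"path": str(p), "sha256": _sha256(p)} for k, p in config.inputs.items()
        }

        stage = "phenotype"
        ph = config.phenotyping
        episodes = sio.read_episode_log(config.inputs["episodes"])
        days = phen.build_day_records(
            episodes, day_rule=ph["day_rule"], main_rule=ph["main_rule"]
        )
        kept, qc_report = phen.apply_qc(
            days, min_daily_tst=ph["min_daily_tst"], min_days=ph["min_days"]
        )
        phenos = phen.summarize(kept)
        phen.standardize_phenotypes(phenos)
        phen_df = phen.phenotypes_to_frame(phenos)
        phen_path = out / "phenotypes.tsv"
        phen_df.to_csv(phen_path, sep="\t", float_format="%.12g")
        with open(out / "phenotype_exclusions.json", "w") as fh:
            json.dump(
                {
                    **{k: v for k, v in qc_report.items() if k != "dropped_days"},
                    "dropped_days": [
                        [pid, d.isoformat()] for pid, d in qc_report["dropped_days"]
                    ],
                },
                fh,
                indent=1,
            )
        manifest["stages"]["phenotype"] = {
            "n_episodes": len(episodes),
            "n_days_input": qc_report["n_input_days"],
            "n_days_dropped": qc_report["n_dropped_days"],
            "n_days_retained": qc_report["n_retained_days"],
            "participants_excluded": qc_report["excluded_participants"],
            "n_participants_retained": len(phen_df),
        }
        log.info(
            "stage=phenotype days_in=%d days_kept=%d participants=%d",
            qc_report["n_input_days"], qc_report["n_retained_days"], len(phen_df),
        )

        stage = "associate"
        npx, npx_report = sio.read_npx_long(config.inputs["npx"])
        covariates = sio.read_covariates(config.inputs["covariates"])
        shared = [p for p in phen_df.index if p in npx.values.index]
        phen_df = phen_df.loc[shared]
        npx.values = npx.values.loc[shared]
        ac = config.association
        manifest["stages"]["npx_qc"] = {
            "n_input_records": npx_report["n_input_records"],
            "n_dropped_records": npx_report["n_dropped_records"],
            "assays_removed": npx_report["assays_removed"],
            "n_assays": len(npx.assay_ids),
            "n_distinct_proteins": len(npx.protein_ids),
        }
        significant: dict[str, list] = {}
        for outcome in ac["outcomes"]:
            results, info = assoc.run_association(
                npx,
                phen_df,
                covariates,
                outcome,
                quadratic=ac["quadratic"],
                lambda_rule=ac["lambda_rule"],
                seed=config.seed,
                q_threshold=ac["q_threshold"],
            )
            sig = [r for r in results if r.q < ac["q_threshold"]]
            significant[outcome] = sig
            if results:
                sio.write_results_table(results, out / f"results_{outcome}.tsv")
                _write_volcano(results, out / f"volcano_{outcome}.tsv")
            manifest["stages"][f"associate_{outcome}"] = {
                "n_assays_screened": info["n_screened"],
                "n_assays_fit": len(results),
                "n_skipped": len(info["skipped_assays"]),
                "n_significant": len(sig),
                "lambda": info["screen"].get("lambda") if info["n_screened"] else None,
            }
            log.info(
                "stage=associate outcome=%s screened=%d significant=%d",
                outcome, info["n_screened"], len(sig),
            )

        stage = "enrich"
        ec = config.enrichment
        genesets = sio.read_gmt(config.inputs["gmt"])
        background = [g.upper() for g in npx.protein_ids]
        queries: dict[str, set[str]] = {}
        if ec["mode"] == "union":
            q = {r.protein_id.upper() for rs in significant.values() for r in rs}
            queries["union"] = q
        else:
            for outcome, rs in significant.items():
                queries[outcome] = {r.protein_id.upper() for r in rs}
        for name, query in queries.items():
            if not query:
                log.warning("stage=enrich query=%s empty; skipped", name)
                manifest["stages"][f"enrich_{name}"] = {"n_query": 0, "n_passed": 0}
                continue
            terms = enr.run_enrichment(
                query,
                background,
                genesets,
                p_max=ec["p_max"],
                min_count=ec["min_count"],
                min_ef=ec["min_ef"],
                kappa_threshold=ec["kappa_threshold"],
            )
            _write_enrichment(terms, out / f"enrichment_{name}.tsv")
            n_passed = sum(t.passed for t in terms)
            manifest["stages"][f"enrich_{name}"] = {
                "n_query": len(query),
                "n_terms_scored": len(terms),
                "n_passed": n_passed,
                "n_clusters": len({t.cluster_id for t in terms if t.passed}),
            }
            log.info("stage=enrich query=%s n=%d passed=%d", name, len(query), n_passed)
    except Exception:
        log.exception("pipeline aborted in stage %s; partial outputs kept in %s",
                      stage, out)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
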