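"""End-to-end orchestration: preprocess -> target attainment ->
trajectories -> sequence clustering -> change analysis, with exclusion-flow
bookkeeping and CSV report outputs.

Every run writes a ``manifest.json`` recording the configuration, the seed,
per-stage row counts (reproducing the patient-selection flowchart) and the
output file list; the counts satisfy the conservation identities checked by
the test suite.
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

from . import change_analysis as ca
from . import preprocess as pp
from . import sequence_clustering as sc
from . import synthetic_data as sd
from . import target_attainment as ta
from . import trajectories as tj
from .ehr_model import CohortConfig, read_tables, table_paths, write_tables

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "simulate_to_dir", "render_report"]


@dataclass
class RunManifest:
    config: dict
    seed: int | None
    input_digests: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    notes: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _config_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["remeasure_date"] = config.remeasure_date.isoformat()
    return d


def simulate_to_dir(gen_config: sd.GeneratorConfig, out_dir: str | Path) -> dict:
    """Generate a synthetic cohort, write its tables and truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables, truth = sd.generate_cohort(gen_config)
    written = write_tables(tables, out_dir)
    truth.to_json(out_dir / "truth.json")
    return {name: str(p) for name, p in written.items()}


def run_pipeline(
    config: CohortConfig,
    input_dir: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Run the full analysis on the tables under ``input_dir``; write all
    report CSVs and the manifest under ``out_dir``."""
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = table_paths(input_dir)
    manifest = RunManifest(
        config=_config_dict(config),
        seed=seed,
        input_digests={name: _digest(p) for name, p in paths.items()},
    )

    def save(name: str, df: pd.DataFrame) -> None:
        path = out_dir / name
        df.to_csv(path, index=False)
        manifest.outputs.append(name)

    tables = read_tables(paths)
    manifest.counts["input_rows"] = {k: int(len(v)) for k, v in tables.items()}

    # ---- preprocess ------------------------------------------------------
    contexts, log = pp.build_contexts(tables, config)
    manifest.counts["flowchart"] = {
        "input_panels": log.input_panels,
        "unreliable": log.unreliable,
        "unreliable_by_reason": {k: int(v) for k, v in log.by_reason.items()},
        "underage": log.underage,
        "non_cvd": log.non_cvd,
        "retained": log.retained,
    }
    if not log.conserves():
        raise RuntimeError("preprocess: exclusion counts do not conserve")
    save("contexts.csv", contexts)
    if contexts.empty:
        manifest.notes.append("no contexts retained; downstream stages skipped")
        manifest.write(out_dir / "manifest.json")
        return manifest

    # ---- target attainment ----------------------------------------------
    first = ta.first_measurements(contexts)
    singles, repeated = ta.split_by_repetition(contexts)
    manifest.counts["patients"] = {
        "total": int(first["patient_id"].nunique()),
        "single": int(singles["patient_id"].nunique()),
        "repeated": int(repeated["patient_id"].nunique()),
    }
    save("baseline_table.csv", ta.baseline_table(contexts, config))
    save("attainment_by_year.csv", ta.attainment_prevalence(contexts, "per_year", config))
    save("attainment_by_stratum.csv", ta.attainment_prevalence(contexts, "per_stratum", config))
    states = ta.ldl_states(first["ldl"].to_numpy(), config.ldl_target)
    hist = pd.Series(states).value_counts().reindex(range(ta.N_STATES), fill_value=0)
    save("state_histogram_first.csv", pd.DataFrame(
        {"state": ta.STATE_LABELS, "n": hist.to_numpy()}))
    try:
        save("offtarget_or.csv", ta.offtarget_logistic(first, config).reset_index(names="covariate"))
    except ta.ModelFitError as exc:
        manifest.notes.append(f"baseline logistic not fitted: {exc}")

    # ---- trajectories ----------------------------------------------------
    linkage = tj.link_measurements(contexts, config)
    manifest.counts["linkage"] = {
        "input_measurements": linkage.n_input_measurements,
        "in_sequences": linkage.n_in_sequences,
        "discarded_unrelated": linkage.n_discarded_unrelated,
        "single_measurement_patients": linkage.n_singleton_input,
        "reduced_to_single": linkage.n_reduced_to_single,
    }
    if not linkage.conserves():
        raise RuntimeError("trajectories: linkage counts do not conserve")
    empty_trajectories = linkage.sequences.empty
    if empty_trajectories:
        manifest.notes.append("trajectory stages not computed: no linked sequences")
        for name in ("sequences.csv", "transition_counts.csv", "transition_probs.csv",
                     "state_distributions.csv"):
            save(name, pd.DataFrame())
    else:
        truncated, k = tj.truncate_sequences(linkage.sequences, config.truncation_percentile)
        manifest.counts["truncation"] = {
            "cutoff_k": k,
            "measurements_after_truncation": int(len(truncated)),
            "patients": int(truncated["patient_id"].nunique()),
        }
        save("sequences.csv", truncated)
        tm_input = truncated if config.transitions_on_truncated else linkage.sequences
        tm = tj.transition_matrix(tm_input)
        counts_df, probs_df = tm.to_frames()
        save("transition_counts.csv", counts_df.reset_index())
        save("transition_probs.csv", probs_df.reset_index())
        save("state_distributions.csv", tj.state_distributions(truncated))

    # ---- sequence clustering --------------------------------------------
    if empty_trajectories:
        manifest.notes.append("clustering not computed: no linked sequences")
        save("clusters.csv", pd.DataFrame())
    else:
        ids, arrays = tj.sequence_arrays(truncated)
        rng = np.random.default_rng(seed if seed is not None else 0)
        if len(ids) > config.max_cluster_sequences:
            pick = np.sort(rng.choice(len(ids), config.max_cluster_sequences, replace=False))
            ids = [ids[i] for i in pick]
            arrays = [arrays[i] for i in pick]
            manifest.notes.append(
                f"clustering on a seeded subsample of {config.max_cluster_sequences} sequences"
            )
        if len(ids) <= config.n_clusters:
            manifest.notes.append("clustering not computed: too few sequences")
            save("clusters.csv", pd.DataFrame())
        else:
            costs = sc.substitution_costs(
                config.substitution_method,
                transition=tm if config.substitution_method == "trate" else None,
                constant_value=config.substitution_constant,
                indel=config.indel_cost,
            )
            D = sc.pairwise_distances(arrays, costs)
            labels, _ = sc.cluster_sequences(D, config.n_clusters)
            save("clusters.csv", pd.DataFrame({"patient_id": ids, "cluster": labels}))
            save("cluster_profiles.csv", sc.cluster_profiles(labels, arrays))
            save("silhouette_by_k.csv", sc.silhouette_by_k(D))
            cov = first.set_index("patient_id").loc[ids].reset_index()
            for col in ("female", "diabetes", "hypertension"):
                cov[col] = cov[col].astype(float)
            cov["smoking_current"] = cov["smoking_current"].map({True: 1.0, False: 0.0})
            try:
                models = sc.cluster_covariate_model(
                    labels, cov,
                    ["age_years", "female", "diabetes", "hypertension", "smoking_current"],
                )
                rows = []
                for c, tab in models.items():
                    tab = tab.reset_index(names="covariate")
                    tab.insert(0, "cluster", c)
                    rows.append(tab)
                if rows:
                    save("cluster_or.csv", pd.concat(rows, ignore_index=True))
            except ta.ModelFitError as exc:
                manifest.notes.append(f"cluster covariate model not fitted: {exc}")

    # ---- change analysis -------------------------------------------------
    if empty_trajectories:
        manifest.notes.append("change analysis not computed: no linked sequences")
        save("change_pairs.csv", pd.DataFrame())
    else:
        pairs = ca.build_change_pairs(linkage.sequences, contexts)
        manifest.counts["change_pairs"] = {
            "pairs": int(len(pairs)),
            "evaluable": int(pairs["evaluable"].sum()),
            "not_evaluable": int((~pairs["evaluable"]).sum()),
        }
        save("change_pairs.csv", pairs)
        try:
            save("deterioration_or.csv",
                 ca.deterioration_logistic(pairs).reset_index(names="covariate"))
        except (ValueError, ta.ModelFitError) as exc:
            manifest.notes.append(f"deterioration logistic not fitted: {exc}")

    manifest.write(out_dir / "manifest.json")
    logger.info("run_pipeline: wrote %d outputs to %s", len(manifest.outputs), out_dir)
    return manifest


def render_report(out_dir: str | Path) -> str:
    """Assemble a plain-text summary from the pipeline output CSVs."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    lines = ["LDL-c management report", "=" * 40, ""]
    flow = manifest["counts"].get("flowchart", {})
    lines.append("Selection flowchart (measurements):")
    for key in ("input_panels", "unreliable", "underage", "non_cvd", "retained"):
        lines.append(f"  {key}: {flow.get(key, 'n/a')}")
    pats = manifest["counts"].get("patients", {})
    lines.append(f"Patients: {pats.get('total', 'n/a')} "
                 f"(single {pats.get('single', 'n/a')}, repeated {pats.get('repeated', 'n/a')})")
    lines.append("")

    def section(title: str, fname: str) -> None:
        lines.append(title)
        lines.append("-" * len(title))
        path = out_dir / fname
        if not path.exists():
            raise FileNotFoundError(f"missing output file: {path}")
        df = pd.read_csv(path) if path.stat().st_size > 1 else pd.DataFrame()
        if df.empty:
            lines.append("  [not computed]")
        else:
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        lines.append("")

    section("Attainment by stratum", "attainment_by_stratum.csv")
    section("Baseline characteristics", "baseline_table.csv")
    if "offtarget_or.csv" in manifest["outputs"]:
        section("Off-target at first measurement (odds ratios)", "offtarget_or.csv")
    if "transition_probs.csv" in manifest["outputs"]:
        section("Transition probabilities", "transition_probs.csv")
    if "state_distributions.csv" in manifest["outputs"]:
        section("State distributions per measurement", "state_distributions.csv")
    if "cluster_profiles.csv" in manifest["outputs"]:
        section("Cluster profiles", "cluster_profiles.csv")
    if "cluster_or.csv" in manifest["outputs"]:
        section("Cluster membership (odds ratios)", "cluster_or.csv")
    if "deterioration_or.csv" in manifest["outputs"]:
        section("Deterioration model (odds ratios)", "deterioration_or.csv")
    if manifest.get("notes"):
        lines.append("Notes:")
        lines.extend(f"  - {n}" for n in manifest["notes"])
    report = "\n".join(lines)
    (out_dir / "report.txt").write_text(report)
    return report
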