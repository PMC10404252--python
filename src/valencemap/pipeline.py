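"""End-to-end pipeline: synthetic data -> behavioral statistics -> spike
classification -> manifold structure -> valence regression -> POR-dynamics
lasso -> Hebbian conditioning model, with versioned text artifacts and a
reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, ephys, hebbian, io, manifold, por, synthetic, valence

__all__ = ["run_pipeline"]

CONDITIONING_ODORS = ("hexanol", "isoamyl_acetate", "benzaldehyde", "citral")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: synthetic.SyntheticConfig,
    outdir,
    seed: int | None = None,
    mc_locust_sims: int = 100,
    n_trace_locusts: int = 10,
) -> dict:
    """Run every stage on a synthetic dataset and write artifacts to
    ``outdir``.  Returns the manifest (also written as manifest.json)."""
    if seed is not None:
        config = replace(config, seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # -- synthetic inputs
    matrix = synthetic.generate_por_matrix(config)
    dataset = synthetic.generate_pn_population(config)
    io.write_por_matrix(matrix, out / "por_matrix.csv")
    io.write_spike_dataset(dataset, out / "spikes.csv", out / "spikes.json")
    (out / "config.json").write_text(config.to_json())

    # -- behavior
    scores = behavior.compute_scores(matrix)
    scores.to_csv(out / "behavior_scores.csv")
    calls = behavior.classify_valence(matrix)
    pd.DataFrame([c.__dict__ for c in calls]).to_csv(out / "valence_calls.csv", index=False)
    stability = {
        str(n): behavior.monte_carlo_locust_subsample(
            matrix, n, n_sims=mc_locust_sims, seed=config.seed + n
        )
        for n in range(2, config.n_locusts + 1, max(1, config.n_locusts // 8))
    }
    io.write_json(stability, out / "behavior_stability.json")

    # -- ephys
    kept = ephys.filter_consistent_pns(dataset)
    classification = ephys.classify_all(dataset)
    classification.to_csv(out / "pn_classification.csv", index=False)
    on_mean = ephys.mean_epoch_response(dataset, dataset.window.on_interval())
    off_mean = ephys.mean_epoch_response(dataset, dataset.window.off_interval())
    tuning = ephys.tuning_and_valence_stats(
        classification, on_mean, off_mean, scores["preference_index"]
    )
    tuning.to_csv(out / "pn_tuning.csv")

    # -- manifold
    binned = ephys.binned_response_matrix(dataset)
    traj = manifold.pca_trajectories(binned)
    tree = manifold.hierarchical_cluster(on_mean.T)
    labels = {o: config.panel_map[o][0] == "appetitive" for o in dataset.odor_ids}
    angles = manifold.valence_angle_scores(on_mean.T, labels)
    angles.to_csv(out / "valence_angles.csv")
    io.write_json(
        {
            "captured_variance_top3": traj.captured_variance,
            "leaf_order": tree.leaf_order,
            "merges": tree.merge_records(),
        },
        out / "manifold.json",
    )

    # -- valence regression (ON and OFF epochs)
    targets = scores.loc[dataset.odor_ids, "norm_score"].to_numpy()
    loocv = {}
    for epoch, mean in (("on", on_mean), ("off", off_mean)):
        res = valence.loocv_predict(mean.T.to_numpy(), targets, odor_ids=dataset.odor_ids)
        loocv[epoch] = res
    io.write_json(
        {
            e: {
                "r_squared": r.r_squared,
                "mse": r.mse,
                "predictions": dict(zip(r.odor_ids, r.predictions)),
            }
            for e, r in loocv.items()
        },
        out / "valence_regression.json",
    )

    # -- POR-dynamics lasso (hexanol-ON paradigm on synthetic traces)
    rng_seed = config.seed + 77
    traces = {}
    for odor in CONDITIONING_ODORS:
        cls = config.panel_map[odor][0]
        vclass = "appetitive" if cls == "appetitive" else "unappetitive"
        traces[odor] = synthetic.generate_por_traces(
            "ON", vclass, config, n_traces=n_trace_locusts, odor_id=odor, seed=rng_seed
        )
    design = por.build_design(dataset.subset_pns(dataset.pn_ids), traces, list(CONDITIONING_ODORS))
    lasso_res = por.PORLasso(design, alpha=0.01).fit()
    io.write_json(
        {
            "weights": lasso_res.params,
            "intercept": lasso_res.intercept,
            "kkt_residual": lasso_res.kkt_residual(),
            "per_odor_r": lasso_res.per_odor_correlations()["r"].to_dict(),
        },
        out / "por_lasso.json",
    )

    # -- Hebbian model
    net = hebbian.HebbianNetwork.from_dataset(
        dataset, CONDITIONING_ODORS[:2], CONDITIONING_ODORS[2:]
    )
    pre = {o: float(net.simulate_por(o)["por"].max()) for o in CONDITIONING_ODORS}
    net.hebbian_update(CONDITIONING_ODORS[0])
    post = {o: float(net.simulate_por(o)["por"].max()) for o in CONDITIONING_ODORS}
    io.write_json({"pre_learning_peak_por": pre, "post_learning_peak_por": post},
                  out / "hebbian.json")

    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "n_pns_retained": len(kept),
        "stages": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        "checksums": {
            p.name: _checksum(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
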