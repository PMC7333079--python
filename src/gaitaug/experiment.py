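"""Experiment driver: simulated pools, augmentation-ratio sweeps, LOSO CV.

The central comparison trains one network per biomechanical variable on
(a) measured cycles only and (b) measured cycles plus r times as many
simulated cycles, drawn equally from each training subject's fitted
distributions, then scores the fixed held-out test subjects.  Ratios are
named by the simulated:measured multiplier (0, 1, 3, 7, 15), so the total
training set is 1, 2, 4, 8, 16 times the measured count.

Simulated pools come from either of two paths:

* ``method='ocp'``: sampled cycle vectors are tracked by the optimal-control
  simulation and expanded to full cycles (dynamically consistent; slow).
* ``method='resynthesis'``: sampled cycle vectors are reconstructed
  kinematically, with inverse-dynamics moments and noise-free virtual sensor
  signals (fast; the desk-scale default).

Both produce noise-free sensor data, unlike the "measured" cycles, so the
measured/simulated reality gap is preserved either way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnn import CNNConfig, build_network, fit_normalization, train
from .cycles import (
    BIOMECH_COLUMNS,
    GaitCycle,
    cycles_to_table,
    imu_matrix,
    table_to_cycles,
)
from .imu import default_sensors, simulate_imu_cycle
from .metrics import (
    VARIABLE_CLASSES,
    pearson_mean,
    pearson_per_cycle,
    rmse,
    stance_masks,
)
from .motion import inverse_dynamics_moments, reconstruct_motion
from .msk.params import Anthropometry, scale_model
from .ocp import CollocationGrid, build_ocp, expand_to_full_cycle, solve_ocp
from .sampler import (
    assemble_cycle_vector,
    disassemble_cycle_vector,
    draw_samples,
    fit_distribution,
    split_tracking,
)

log = logging.getLogger(__name__)

DEFAULT_RATIOS = (0, 1, 3, 7, 15)


@dataclass
class ExperimentPlan:
    """One augmentation experiment: fixed test subjects, ratio and seed sweeps."""

    train_subjects: tuple
    test_subjects: tuple
    ratios: tuple = DEFAULT_RATIOS
    seeds: tuple = tuple(range(10))
    sim_per_dist: int = 1000
    variables: tuple = tuple(VARIABLE_CLASSES)
    cnn: CNNConfig = field(default_factory=CNNConfig)

    def __post_init__(self):
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(f"train and test subjects overlap: {sorted(overlap)}")


def training_set_size(n_measured: int, ratio: int) -> int:
    """Total training samples at a simulated:measured ratio r: n * (1 + r)."""
    return n_measured * (1 + ratio)


# ---------------------------------------------------------------------------
# simulated pools
# ---------------------------------------------------------------------------


def fit_subject_distributions(dataset: pd.DataFrame, subjects) -> dict:
    """Per (subject, gait) multivariate-normal fits from measured cycles."""
    cycles = table_to_cycles(dataset[dataset["subject_id"].isin(subjects)])
    dists = {}
    for sid in subjects:
        for gait in ("walk", "run"):
            Z = [
                assemble_cycle_vector(c)
                for c in cycles
                if c.subject_id == sid and c.gait == gait and c.source == "measured"
            ]
            if len(Z) >= 2:
                dists[(sid, gait)] = fit_distribution(np.stack(Z), sid, gait)
    return dists


def _sample_to_cycle_resynthesis(z, model, sid, trial, gait) -> GaitCycle:
    ch = disassemble_cycle_vector(z)
    motion = reconstruct_motion(
        ch["hip_angle"], ch["knee_angle"], ch["ankle_angle"],
        ch["grf_ap"], ch["grf_v"], ch["speed"], model, gait,
    )
    moments = inverse_dynamics_moments(motion, ch["grf_ap"], ch["grf_v"])
    imu = simulate_imu_cycle(motion, default_sensors(model))
    return GaitCycle(
        subject_id=sid, gait=gait, speed=ch["speed"],
        bw=model.body_weight, bh=model.body_height,
        hip_angle=ch["hip_angle"], knee_angle=ch["knee_angle"], ankle_angle=ch["ankle_angle"],
        grf_ap=ch["grf_ap"], grf_v=ch["grf_v"],
        hip_moment=moments[:, 0], knee_moment=moments[:, 1], ankle_moment=moments[:, 2],
        imu=imu, trial=trial, source="simulated",
    )


def _sample_to_cycle_ocp(z, dist, model, sid, trial, n_nodes, solver_kw) -> GaitCycle | None:
    targets = split_tracking(z, dist, n_nodes=n_nodes)
    nlp = build_ocp(targets, model, CollocationGrid(n_nodes=n_nodes), mode="torque")
    result = solve_ocp(nlp, **solver_kw)
    if result.status != "converged":
        return None
    cycle, motion = expand_to_full_cycle(result, nlp, subject_id=sid, trial=trial)
    cycle.gait = dist.gait  # label by source distribution, not sampled speed
    cycle.imu = simulate_imu_cycle(motion, default_sensors(model))
    return cycle


def make_simulated_pool(
    dataset: pd.DataFrame,
    subjects,
    n_per_dist: int,
    seed: int,
    method: str = "resynthesis",
    n_nodes: int = 20,
    max_redraws: int = 3,
    solver_kw: dict | None = None,
) -> pd.DataFrame:
    """Simulated cycles: ``n_per_dist`` per (training subject, gait) distribution.

    Simulated data is drawn only from the given (training) subjects.  With
    ``method='ocp'``, samples whose simulation fails to converge are redrawn
    up to ``max_redraws`` times and failure counts logged.
    """
    if method not in ("resynthesis", "ocp"):
        raise ValueError(f"unknown pool method {method!r}")
    dists = fit_subject_distributions(dataset, subjects)
    if not dists:
        raise ValueError("no fittable (subject, gait) groups among the given subjects")
    meta = dataset.drop_duplicates("subject_id").set_index("subject_id")

    out, n_failed = [], 0
    for gi, ((sid, gait), dist) in enumerate(sorted(dists.items())):
        model = scale_model(Anthropometry(meta.loc[sid, "bw_kg"], meta.loc[sid, "bh_m"]))
        sub_seed = [seed, gi]  # deterministic per (seed, subject, gait)
        Z, _ = draw_samples(dist, n_per_dist * (1 + (max_redraws if method == "ocp" else 0)), sub_seed)
        made = 0
        for zi, z in enumerate(Z):
            if made >= n_per_dist:
                break
            if method == "resynthesis":
                out.append(_sample_to_cycle_resynthesis(z, model, sid, trial=made, gait=gait))
                made += 1
            else:
                cyc = _sample_to_cycle_ocp(z, dist, model, sid, made, n_nodes, solver_kw or {})
                if cyc is None:
                    n_failed += 1
                    continue
                out.append(cyc)
                made += 1
        if made < n_per_dist:
            log.warning("pool for %s/%s short: %d of %d", sid, gait, made, n_per_dist)
    if n_failed:
        log.info("simulated pool: %d non-converged samples redrawn/skipped", n_failed)
    return cycles_to_table(out)


# ---------------------------------------------------------------------------
# training-set assembly and scoring
# ---------------------------------------------------------------------------


def assemble_training_set(
    measured: pd.DataFrame, pool: pd.DataFrame, ratio: int, seed: int
) -> pd.DataFrame:
    """Measured cycles plus ratio x as many simulated ones, equal per subject/gait.

    Simulated cycles are picked randomly (seeded) from the pool; the per-group
    draw counts differ by at most one.  Raises if the pool is too small.
    """
    if ratio == 0:
        return measured
    X_meta = measured.drop_duplicates(subset=["subject_id", "gait", "trial", "source", "speed_mps"])
    n_meas = len(X_meta)
    n_sim = n_meas * ratio
    groups = list(pool.groupby(["subject_id", "gait"], sort=True).groups)
    if not groups:
        raise ValueError("empty simulated pool")
    base, extra = divmod(n_sim, len(groups))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(groups))
    take = {groups[gi]: base + (1 if rank < extra else 0) for rank, gi in enumerate(order)}

    picked = []
    for g, df_g in pool.groupby(["subject_id", "gait"], sort=True):
        keys = df_g.drop_duplicates(subset=["trial", "speed_mps"])[["trial", "speed_mps"]]
        want = take[g]
        if want > len(keys):
            raise ValueError(
                f"pool for {g} has {len(keys)} cycles but {want} requested; enlarge the pool"
            )
        sel = keys.iloc[rng.choice(len(keys), size=want, replace=False)]
        picked.append(df_g.merge(sel, on=["trial", "speed_mps"]))
    return pd.concat([measured] + picked, ignore_index=True)


def _score(est, Y_ref, var, meta, masks) -> tuple:
    cls = VARIABLE_CLASSES[var]
    m = masks if cls == "grf" else None
    r = rmse(est, Y_ref, cls, bw=meta["bw_kg"].to_numpy(), bh=meta["bh_m"].to_numpy(), mask=m)
    p = pearson_mean(pearson_per_cycle(est, Y_ref, mask=m))
    return r, p


def run_experiment(
    plan: ExperimentPlan, dataset: pd.DataFrame, pool: pd.DataFrame | None
) -> pd.DataFrame:
    """Ratio x seed sweep; per-test-subject and pooled metrics.

    Returns a long table (variable, ratio, seed, subject, rmse, pearson,
    n_train); subject 'ALL' rows pool every test cycle before computing the
    metric.  Train/test disjointness is asserted on entry.
    """
    train_ids, test_ids = set(plan.train_subjects), set(plan.test_subjects)
    assert not (train_ids & test_ids), "train/test subjects overlap"
    measured = dataset[
        (dataset["source"] == "measured") & dataset["subject_id"].isin(train_ids)
    ]
    test_df = dataset[
        (dataset["source"] == "measured") & dataset["subject_id"].isin(test_ids)
    ]
    if measured.empty or test_df.empty:
        raise ValueError("empty measured training or test set for the given subjects")
    X_test, Y_test, meta_test = imu_matrix(test_df)
    masks_test = stance_masks(Y_test["grf_v_bw"])

    rows = []
    for ratio in plan.ratios:
        if ratio > 0 and pool is None:
            raise ValueError("nonzero ratios require a simulated pool")
        for seed in plan.seeds:
            train_df = assemble_training_set(measured, pool, ratio, seed) if ratio else measured
            X_tr, Y_tr, _ = imu_matrix(train_df)
            norm = fit_normalization(X_tr)
            for var in plan.variables:
                net = build_network(plan.cnn, seed=seed)
                est = train(
                    net, X_tr, Y_tr[var], plan.cnn, seed=seed, variable=var, norm=norm
                )
                pred = est.predict(X_test)
                r_all, p_all = _score(pred, Y_test[var], var, meta_test, masks_test)
                rows.append(
                    dict(variable=var, ratio=ratio, seed=seed, subject="ALL",
                         rmse=r_all, pearson=p_all, n_train=X_tr.shape[0])
                )
                for sid in sorted(test_ids):
                    sel = (meta_test["subject_id"] == sid).to_numpy()
                    r_s, p_s = _score(
                        pred[sel], Y_test[var][sel], var, meta_test[sel], masks_test[sel]
                    )
                    rows.append(
                        dict(variable=var, ratio=ratio, seed=seed, subject=sid,
                             rmse=r_s, pearson=p_s, n_train=X_tr.shape[0])
                    )
    return pd.DataFrame(rows)


def loso_cv(
    dataset: pd.DataFrame,
    subjects,
    cnn: CNNConfig,
    pool: pd.DataFrame | None = None,
    ratios=(0,),
    seeds=(0,),
    variables=tuple(VARIABLE_CLASSES),
) -> pd.DataFrame:
    """Leave-one-subject-out cross-validation over the given subjects.

    Each subject serves once as the validation fold; simulated data (when a
    pool is supplied) is restricted to the remaining training subjects.
    """
    frames = []
    for held_out in subjects:
        rest = tuple(s for s in subjects if s != held_out)
        plan = ExperimentPlan(
            train_subjects=rest,
            test_subjects=(held_out,),
            ratios=tuple(ratios),
            seeds=tuple(seeds),
            variables=tuple(variables),
            cnn=cnn,
        )
        fold_pool = None
        if pool is not None:
            fold_pool = pool[pool["subject_id"].isin(rest)]
        res = run_experiment(plan, dataset, fold_pool)
        res["fold"] = held_out
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
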