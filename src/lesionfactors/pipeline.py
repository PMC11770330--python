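"""Study orchestration: simulate -> map-lesions -> disconnect -> factorize
-> associate -> report, as one seeded, manifest-tracked run.

The in-memory analysis helpers (:func:`factor_association_scan`,
:func:`lrt_added_value`, :func:`cca_domains`, :func:`longitudinal_model`)
are the library surface the file-based stages are built on; tests and the
acceptance harness call them directly.

Two disconnection-corpus routes coexist by design.  The *model* route
draws counts from the exact factor generative model (planted loadings
drive the cognitive outcomes), so estimator recovery is attributable to
the estimator; the *geometric* route (lesion masks -> streamline
intersection -> pseudo-count encoding) exercises the full measurement
chain.  ``factorize`` consumes the model corpus by default and the
geometric profiles on request.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lfio
from .association_stats import (
    SeparationError,
    bh_fdr,
    cca_first,
    fit_logistic,
    fit_logistic_mixed,
    lr_test,
    transition_table,
)
from .disconnectome import profiles_for_masks
from .latent_factors import encode_pseudocounts, factor_load_share, fit_lda, select_k
from .lesion_mapping import (
    bullseye_parcellation,
    incidence_map,
    lesion_volume,
    normalize_volume,
    parcel_loads,
    territory_volumes,
)
from .synth import (
    DOMAINS,
    SynthConfig,
    make_atlas,
    make_template,
    sample_cognition,
    sample_disconnection_corpus,
    sample_lesions,
)

__all__ = [
    "RunConfig",
    "stage_seed",
    "run_pipeline",
    "report",
    "factor_association_scan",
    "lrt_added_value",
    "cca_domains",
    "longitudinal_model",
    "simulate_study",
]

_STAGES = ("simulate", "map_lesions", "disconnect", "factorize", "associate")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of (master seed, stage name)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    synth: dict = field(default_factory=dict)
    step_mm: float | None = None
    scale: float = 10.0
    k_min: int = 2
    k_max: int = 6
    n_runs: int = 5
    lda_alpha: float | None = None
    lda_eta: float = 0.01
    n_perm: int = 1999
    fdr_q: float = 0.05
    corpus_source: str = "model"  # "model" or "geometric"
    force: bool = False

    def __post_init__(self) -> None:
        known = set(SynthConfig.__dataclass_fields__)
        unknown = set(self.synth) - known
        if unknown:
            raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
        if self.corpus_source not in ("model", "geometric"):
            raise ValueError("corpus_source must be 'model' or 'geometric'")
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def synth_config(self) -> SynthConfig:
        kwargs = dict(self.synth)
        kwargs.setdefault("seed", stage_seed(self.seed, "simulate"))
        return SynthConfig(**kwargs)


# --------------------------------------------------------------------------
# in-memory study simulation and analysis
# --------------------------------------------------------------------------

def simulate_study(config: SynthConfig, with_geometry: bool = True) -> dict:
    """Generate one complete synthetic study.

    Returns a dict with the template, atlas, lesion masks (both kinds),
    exact-model corpora for both lesion kinds (the WMH corpus carries the
    causal factor; infarct loadings are independent of outcome), the
    planted truths, and the cohort table.
    """
    seed = config.seed
    out: dict = {"config": config}
    if with_geometry:
        template = make_template(config.grid_shape, config.voxel_mm, seed=seed)
        atlas = make_atlas(template, config.n_tracts, config.streamlines_per_tract, seed=seed + 1)
        out["template"] = template
        out["atlas"] = atlas
        out["masks"] = {
            kind: sample_lesions(template, kind, config.n_subjects, seed=seed + 2 + i)
            for i, kind in enumerate(("infarct", "wmh"))
        }
    from dataclasses import replace

    wmh_cfg = replace(config, seed=seed + 10)
    inf_cfg = replace(config, seed=seed + 11)
    counts_wmh, truth_wmh = sample_disconnection_corpus(wmh_cfg)
    counts_inf, truth_inf = sample_disconnection_corpus(inf_cfg)
    out["corpus"] = {"wmh": counts_wmh, "infarct": counts_inf}
    out["truth"] = {"wmh": truth_wmh, "infarct": truth_inf}
    out["cohort"] = sample_cognition(truth_wmh.theta_true, config, seed=seed + 12)
    return out


def _design(cohort: pd.DataFrame, cols: list[str]) -> np.ndarray:
    return np.column_stack([np.ones(len(cohort))] + [cohort[c].to_numpy(float) for c in cols])


def factor_association_scan(
    cohort: pd.DataFrame,
    loadings: dict[str, np.ndarray],
    timepoints: tuple[int, ...] = (6, 36),
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-factor logistic tests of impairment status, FDR per timepoint.

    For each timepoint and each lesion kind's factor loadings, fits
    ``psci ~ loading_k + age + education`` one factor at a time and
    applies Benjamini-Hochberg correction within the timepoint's family
    (all kinds and factors together).
    """
    rows = []
    for tp in timepoints:
        y = cohort[f"psci_m{tp}"].to_numpy(int)
        base = _design(cohort, ["age", "education"])
        for kind, theta in loadings.items():
            theta = np.asarray(theta, float)
            for k in range(theta.shape[1]):
                X = np.column_stack([base[:, :1], theta[:, k], base[:, 1:]])
                try:
                    fit = fit_logistic(y, X, names=["intercept", "loading", "age", "education"])
                    coef, se, pval = fit.coef[1], fit.se[1], fit.p[1]
                    orr = fit.or_[1]
                except (SeparationError, ValueError):
                    coef = se = pval = orr = np.nan
                rows.append(
                    {"timepoint": tp, "kind": kind, "factor": k + 1,
                     "coef": coef, "se": se, "or": orr, "p": pval}
                )
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    df["reject"] = False
    for tp in timepoints:
        sel = (df["timepoint"] == tp) & df["p"].notna()
        if sel.any():
            p_adj, rej = bh_fdr(df.loc[sel, "p"].to_numpy(), q=q)
            df.loc[sel, "p_adj"] = p_adj
            df.loc[sel, "reject"] = rej
    return df


def lrt_added_value(cohort: pd.DataFrame, loading: np.ndarray, timepoint: int) -> dict:
    """Added value of a factor loading over demographic/clinical predictors.

    Compares ``psci ~ moca + wmh + loading + age + education`` against the
    model without the loading via a likelihood-ratio test (df = 1).
    """
    y = cohort[f"psci_m{timepoint}"].to_numpy(int)
    base_cols = ["moca", "wmh_cm3", "age", "education"]
    X_red = _design(cohort, base_cols)
    X_full = np.column_stack([X_red[:, :3], np.asarray(loading, float), X_red[:, 3:]])
    full = fit_logistic(y, X_full, names=["intercept", "moca", "wmh", "loading", "age", "education"])
    red = fit_logistic(y, X_red, names=["intercept", "moca", "wmh", "age", "education"])
    chi2, p = lr_test(full.loglik, red.loglik, df_diff=1)
    return {
        "timepoint": timepoint,
        "loglik_full": full.loglik,
        "loglik_reduced": red.loglik,
        "chi2": chi2,
        "p": p,
        "full": full,
        "reduced": red,
    }


def cca_domains(
    cohort: pd.DataFrame,
    loading: np.ndarray,
    timepoint: int,
    n_perm: int = 1999,
    seed: int = 0,
):
    """First canonical correlation: four domain z-scores vs one loading."""
    X = cohort[[f"z_{d}_m{timepoint}" for d in DOMAINS]].to_numpy(float)
    return cca_first(X, np.asarray(loading, float), n_perm=n_perm, seed=seed)


def longitudinal_model(cohort: pd.DataFrame, loading: np.ndarray, n_nodes: int = 15):
    """Random-intercept logistic model of status across both timepoints."""
    long = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject_id": cohort["subject_id"],
                    "psci": cohort[f"psci_m{tp}"],
                    "time": 0.0 if tp == 6 else 1.0,
                    "loading": np.asarray(loading, float),
                    "age": cohort["age"],
                    "education": cohort["education"],
                }
            )
            for tp in (6, 36)
        ],
        ignore_index=True,
    )
    return fit_logistic_mixed(long, n_nodes=n_nodes)


# --------------------------------------------------------------------------
# file-based stages
# --------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _outputs_fresh(manifest: dict, stage: str, out: Path) -> bool:
    rec = manifest.get("stages", {}).get(stage)
    if not rec:
        return False
    for rel, digest in rec.get("outputs", {}).items():
        p = out / rel
        if not p.exists() or _sha256(p) != digest:
            return False
    return True


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, skipping stages whose outputs are up to date.

    Returns the run manifest (also written to ``manifest.json``): config
    snapshot, package version, per-stage output checksums and timings.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    old_manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest: dict = {
        "config": {**asdict(config), "out_dir": str(config.out_dir)},
        "version": __version__,
        "stages": {},
    }
    state: dict = {}
    for stage in _STAGES:
        fn = globals()[f"_stage_{stage}"]
        t0 = time.perf_counter()
        if not config.force and _outputs_fresh(old_manifest, stage, out):
            rec = dict(old_manifest["stages"][stage])
            rec["skipped"] = True
            manifest["stages"][stage] = rec
            _load_stage_state(stage, out, state, config)
            continue
        try:
            outputs = fn(config, out, state)
        except Exception as exc:
            manifest["stages"][stage] = {"error": str(exc)}
            manifest_path.write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "outputs": {rel: _sha256(out / rel) for rel in outputs},
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "skipped": False,
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _load_stage_state(stage: str, out: Path, state: dict, config: RunConfig) -> None:
    """Rehydrate in-memory state for a skipped stage from its outputs."""
    if stage == "simulate":
        state["template"] = lfio.load_template(out / "template")
        state["atlas"] = lfio.load_atlas(out / "atlas")
        state["cohort"] = pd.read_csv(out / "cohort.csv")
        state["masks"] = {
            kind: [
                lfio.load_mask(p, kind=kind)
                for p in sorted((out / "masks" / kind).glob("*.nii"))
            ]
            for kind in ("infarct", "wmh")
        }
        state["corpus"] = {}
        for kind in ("infarct", "wmh"):
            mat, names, sids = lfio.load_profiles(out / f"model_corpus_{kind}.csv")
            from .latent_factors import DisconnectionCorpus

            state["corpus"][kind] = DisconnectionCorpus(
                counts=mat.astype(np.int64), tract_names=names, subject_ids=sids
            )
        truth = json.loads((out / "truth.json").read_text())
        state["truth_theta"] = {k: np.asarray(v["theta_true"]) for k, v in truth.items()}
    elif stage == "factorize":
        state["theta_hat"] = {}
        state["factor_meta"] = {}
        for kind in ("infarct", "wmh"):
            mat, _, _ = lfio.load_profiles(out / f"theta_{kind}.csv")
            state["theta_hat"][kind] = mat
            state["factor_meta"][kind] = json.loads((out / f"factors_{kind}.json").read_text())


def _stage_simulate(config: RunConfig, out: Path, state: dict) -> list[str]:
    scfg = config.synth_config()
    study = simulate_study(scfg)
    state.update(study)
    state["truth_theta"] = {k: study["truth"][k].theta_true for k in study["truth"]}
    outputs: list[str] = []
    lfio.save_template(study["template"], out / "template")
    outputs += [f"template/{n}.nii.gz" for n in ("brain", "ventricles", "cortex", "lobes", "territories")]
    lfio.save_atlas(study["atlas"], out / "atlas")
    outputs += ["atlas/atlas.json", "atlas/coords.npz"]
    for kind, masks in study["masks"].items():
        (out / "masks" / kind).mkdir(parents=True, exist_ok=True)
        for m in masks:
            lfio.save_mask(m, out / "masks" / kind / f"{m.subject_id}.nii")
            outputs.append(f"masks/{kind}/{m.subject_id}.nii")
    names = study["atlas"].tract_names
    sids = study["cohort"]["subject_id"].tolist()
    for kind in ("infarct", "wmh"):
        lfio.save_profiles(study["corpus"][kind], names, sids, out / f"model_corpus_{kind}.csv")
        outputs.append(f"model_corpus_{kind}.csv")
    study["cohort"].to_csv(out / "cohort.csv", index=False)
    outputs.append("cohort.csv")
    truth = {
        kind: {
            "beta_true": study["truth"][kind].beta_true.tolist(),
            "theta_true": study["truth"][kind].theta_true.tolist(),
            "causal_factor_index": study["truth"][kind].causal_factor_index,
            "outcome_coeffs": study["truth"][kind].outcome_coeffs,
        }
        for kind in ("infarct", "wmh")
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    outputs.append("truth.json")
    # keep the corpora as DisconnectionCorpus objects for later stages
    from .latent_factors import DisconnectionCorpus

    state["corpus"] = {
        kind: DisconnectionCorpus(counts=study["corpus"][kind], tract_names=names, subject_ids=sids)
        for kind in ("infarct", "wmh")
    }
    return outputs


def _stage_map_lesions(config: RunConfig, out: Path, state: dict) -> list[str]:
    template = state["template"]
    cohort = state["cohort"]
    icv = cohort["icv_cm3"].to_numpy(float)
    mean_icv = float(icv.mean())
    parc = bullseye_parcellation(template)
    rows = []
    for kind in ("infarct", "wmh"):
        for m, subject_icv in zip(state["masks"][kind], icv):
            raw = lesion_volume(m)
            vols, dom = territory_volumes(m, template)
            row = {
                "subject_id": m.subject_id,
                "kind": kind,
                "raw_cm3": raw,
                "normalized_cm3": normalize_volume(raw, subject_icv, mean_icv),
                "dominant_territory": dom,
            }
            row.update({f"territory_{i+1}_cm3": v for i, v in enumerate(vols)})
            if kind == "wmh":
                loads = parcel_loads(m, parc)
                row.update({f"parcel_{i+1}_cm3": v for i, v in enumerate(loads)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "volumes.csv", index=False, float_format="%.6g")
    outputs = ["volumes.csv"]
    import nibabel as nib

    for kind in ("infarct", "wmh"):
        inc = incidence_map(state["masks"][kind])
        nib.save(nib.Nifti1Image(inc.astype(np.int16), template.affine), str(out / f"incidence_{kind}.nii"))
        outputs.append(f"incidence_{kind}.nii")
    return outputs


def _stage_disconnect(config: RunConfig, out: Path, state: dict) -> list[str]:
    template = state["template"]
    atlas = state["atlas"]
    outputs = []
    state["geometric_profiles"] = {}
    for kind in ("infarct", "wmh"):
        masks = state["masks"][kind]
        mat = profiles_for_masks(atlas, [m.grid for m in masks], template.affine, step_mm=config.step_mm)
        state["geometric_profiles"][kind] = mat
        lfio.save_profiles(mat, atlas.tract_names, [m.subject_id for m in masks], out / f"profiles_{kind}.csv")
        outputs.append(f"profiles_{kind}.csv")
    return outputs


def _stage_factorize(config: RunConfig, out: Path, state: dict) -> list[str]:
    seed = stage_seed(config.seed, "factorize")
    outputs = []
    state["theta_hat"] = {}
    state["factor_meta"] = {}
    for kind in ("infarct", "wmh"):
        if config.corpus_source == "model":
            corpus = state["corpus"][kind]
        else:
            corpus, _ = encode_pseudocounts(
                state["geometric_profiles"][kind],
                scale=config.scale,
                tract_names=state["atlas"].tract_names,
            )
        rep = select_k(
            corpus, config.k_min, config.k_max, n_runs=config.n_runs, seed=seed,
            alpha=config.lda_alpha, eta=config.lda_eta,
        )
        model = fit_lda(corpus, rep.selected_k, alpha=config.lda_alpha, eta=config.lda_eta, seed=seed)
        top = []
        for k in range(model.k):
            names_k, share = factor_load_share(model.beta[k], min(10, len(corpus.tract_names)), corpus.tract_names)
            top.append({"factor": k + 1, "top_tracts": names_k, "top10_share": share})
        meta = {
            "kind": kind,
            "selected_k": rep.selected_k,
            "k_values": rep.k_values,
            "stability": rep.stability,
            "alpha": model.alpha,
            "eta": model.eta,
            "seed": seed,
            "elbo": model.elbo,
            "n_iter": model.n_iter,
            "converged": model.converged,
            "corpus_source": config.corpus_source,
            "stability_metric": "pairwise optimal-assignment mean Pearson correlation of factor signatures",
            "excluded_subjects": model.excluded_subjects,
            "factors": top,
        }
        (out / f"factors_{kind}.json").write_text(json.dumps(meta, indent=2))
        lfio.save_profiles(model.beta, corpus.tract_names, [f"factor_{k+1}" for k in range(model.k)], out / f"beta_{kind}.csv")
        lfio.save_profiles(model.theta, [f"factor_{k+1}" for k in range(model.k)], corpus.subject_ids, out / f"theta_{kind}.csv")
        outputs += [f"factors_{kind}.json", f"beta_{kind}.csv", f"theta_{kind}.csv"]
        state["theta_hat"][kind] = model.theta
        state["factor_meta"][kind] = meta
    return outputs


def _stage_associate(config: RunConfig, out: Path, state: dict) -> list[str]:
    seed = stage_seed(config.seed, "associate")
    cohort = state["cohort"]
    theta = state["theta_hat"]
    scan = factor_association_scan(cohort, theta, q=config.fdr_q)
    scan.to_csv(out / "factor_scan.csv", index=False, float_format="%.6g")

    # causal candidate: the WMH factor with the strongest positive
    # association at either timepoint, preferring FDR-surviving ones
    wmh = scan[scan["kind"] == "wmh"].reset_index(drop=True)
    wmh = wmh.assign(p=wmh["p"].fillna(1.0))
    sig = wmh[wmh["reject"] & (wmh["coef"] > 0)]
    pick = int((sig if len(sig) else wmh).sort_values("p").iloc[0]["factor"]) - 1
    loading = theta["wmh"][:, pick]

    # small or degenerate cohorts cannot support every model; record the
    # failure per analysis instead of aborting the stage
    results: dict = {"causal_candidate_factor": pick + 1}
    results["lrt"] = {}
    for tp in (6, 36):
        try:
            r = lrt_added_value(cohort, loading, tp)
            results["lrt"][f"m{tp}"] = {
                "loglik_full": r["loglik_full"],
                "loglik_reduced": r["loglik_reduced"],
                "chi2": r["chi2"],
                "p": r["p"],
            }
        except (SeparationError, ValueError, np.linalg.LinAlgError) as exc:
            results["lrt"][f"m{tp}"] = {"error": str(exc)}
    results["cca"] = {}
    for tp in (6, 36):
        try:
            c = cca_domains(cohort, loading, tp, n_perm=config.n_perm, seed=seed)
            results["cca"][f"m{tp}"] = {
                "r1": c.r1,
                "perm_p": c.perm_p,
                "n_perm": c.n_perm,
                "x_weights": c.x_weights.tolist(),
            }
        except ValueError as exc:
            results["cca"][f"m{tp}"] = {"error": str(exc)}
    try:
        mixed = longitudinal_model(cohort, loading)
        results["mixed"] = {
            "names": mixed.names,
            "coef": mixed.coef.tolist(),
            "se": mixed.se.tolist(),
            "or": mixed.or_.tolist(),
            "p": mixed.p.tolist(),
            "re_var": mixed.re_var,
            "converged": mixed.converged,
        }
    except (ValueError, RuntimeError, np.linalg.LinAlgError) as exc:
        results["mixed"] = {"error": str(exc)}
    tt = transition_table(cohort["psci_m6"], cohort["psci_m36"])
    results["transition"] = {
        "both": tt.both,
        "six_only": tt.six_only,
        "thirtysix_only": tt.thirtysix_only,
        "neither": tt.neither,
        "month6_total": tt.month6_total,
        "month36_total": tt.month36_total,
        "converters": tt.converters,
    }
    (out / "associations.json").write_text(json.dumps(results, indent=2))
    state["associations"] = results
    return ["factor_scan.csv", "associations.json"]


def report(out_dir) -> Path:
    """Render a Markdown summary of a completed run."""
    out = Path(out_dir)
    for req in ("factors_wmh.json", "associations.json", "factor_scan.csv"):
        if not (out / req).exists():
            raise FileNotFoundError(f"missing stage output {req}; run the pipeline first")
    lines = ["# Synthetic study report", ""]
    for kind in ("infarct", "wmh"):
        meta = json.loads((out / f"factors_{kind}.json").read_text())
        lines.append(f"## Latent factors — {kind}")
        lines.append(f"Selected K = {meta['selected_k']} "
                     f"(stability: {', '.join(f'K={k}: {s:.3f}' for k, s in zip(meta['k_values'], meta['stability']))})")
        lines.append("")
        for fac in meta["factors"]:
            lines.append(f"### Factor {fac['factor']} — top-10 load share {fac['top10_share']:.2f}")
            lines.append("")
            lines.append("| rank | tract |")
            lines.append("|---|---|")
            for i, t in enumerate(fac["top_tracts"][:5], 1):
                lines.append(f"| {i} | {t} |")
            lines.append("")
    assoc = json.loads((out / "associations.json").read_text())
    scan = pd.read_csv(out / "factor_scan.csv")
    lines.append("## Factor-status logistic scan")
    lines.append("")
    lines.append(scan.to_markdown(index=False))
    lines.append("")
    lines.append("## Added value (likelihood-ratio tests)")
    for tp, r in assoc["lrt"].items():
        if "error" in r:
            lines.append(f"- {tp}: not estimable ({r['error']})")
        else:
            lines.append(f"- {tp}: chi2 = {r['chi2']:.2f}, p = {r['p']:.4f} "
                         f"(logliks {r['loglik_full']:.3f} vs {r['loglik_reduced']:.3f})")
    lines.append("")
    lines.append("## Canonical correlation (domains vs causal loading)")
    for tp, r in assoc["cca"].items():
        if "error" in r:
            lines.append(f"- {tp}: not estimable ({r['error']})")
        else:
            lines.append(f"- {tp}: r1 = {r['r1']:.3f}, permutation p = {r['perm_p']:.4f}")
    lines.append("")
    m = assoc["mixed"]
    lines.append("## Longitudinal random-intercept model")
    lines.append("")
    if "error" in m:
        lines.append(f"Not estimable ({m['error']})")
    else:
        lines.append("| term | coef | se | OR | p |")
        lines.append("|---|---|---|---|---|")
        for nm, c, s, o, p in zip(m["names"], m["coef"], m["se"], m["or"], m["p"]):
            lines.append(f"| {nm} | {c:.3f} | {s:.3f} | {o:.2f} | {p:.3f} |")
        lines.append(f"\nRandom-intercept variance: {m['re_var']:.3f}")
    t = assoc["transition"]
    lines.append("")
    lines.append("## Status transitions (month 6 -> month 36)")
    lines.append(f"- impaired at both: {t['both']}; month 6 only: {t['six_only']}; "
                 f"month 36 only: {t['thirtysix_only']}; neither: {t['neither']}")
    lines.append(f"- marginals: {t['month6_total']} impaired at month 6, "
                 f"{t['month36_total']} at month 36; converters: {t['converters']}")
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
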