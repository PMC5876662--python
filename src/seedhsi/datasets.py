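"""Assembly of the four spectral datasets (ventral, reverse, mean, mixture)
and the mixture-proportion configurations.

Ventral/reverse/mean datasets carry one row per seed. The mixture dataset
trains on both sides of every calibration seed (two rows per seed) and
predicts on a configurable split of the prediction seeds into a
ventral-contributing and a disjoint reverse-contributing subset, so every
prediction row still comes from an unseen seed. The five standard
proportion configurations are (ventral, reverse) = (27, 27), (0, 27),
(13, 27), (27, 13), (27, 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NONVIABLE, VIABLE, SeedSpectrum, SpectralDataset
from .synthetic import Population

TABLE1_CONFIGS = ((27, 27), (0, 27), (13, 27), (27, 13), (27, 0))


@dataclass(frozen=True)
class MixtureConfig:
    n_pred_ventral: int = 27
    n_pred_reverse: int = 27
    assignment_seed: int = 0

    def __post_init__(self) -> None:
        for n in (self.n_pred_ventral, self.n_pred_reverse):
            if n < 0:
                raise ValueError("mixture counts must be >= 0")


def _index_spectra(spectra: list[SeedSpectrum]) -> dict[str, dict[str, SeedSpectrum]]:
    by_seed: dict[str, dict[str, SeedSpectrum]] = {}
    for s in spectra:
        by_seed.setdefault(s.seed_id, {})[s.side] = s
    for seed_id, sides in by_seed.items():
        missing = {"ventral", "reverse"} - set(sides)
        if missing:
            raise ValueError(f"seed {seed_id} is missing its {missing.pop()} spectrum")
    return by_seed


def _assemble(kind, rows, wavelengths) -> SpectralDataset:
    X = np.vstack([r[0] for r in rows])
    meta = pd.DataFrame([r[1] for r in rows])
    return SpectralDataset(
        kind=kind, X=X,
        y=meta["label"].to_numpy(), roles=meta["role"].to_numpy(),
        wavelengths=wavelengths,
        meta=meta[["seed_id", "side"]],
    )


def build_dataset(
    spectra: list[SeedSpectrum] | Population,
    kind: str,
    mixture_config: MixtureConfig | str | None = None,
) -> SpectralDataset:
    """Build one of the four dataset kinds from a two-side spectra collection.

    For ``kind="mixture"`` the prediction rows follow ``mixture_config``
    (default (27, 27)); calibration rows are both sides of every calibration
    seed. Pass ``mixture_config="both-sides"`` to keep every prediction row
    and choose proportions later with :func:`apply_mixture_config`.
    """
    if isinstance(spectra, Population):
        spectra = spectra.spectra
    by_seed = _index_spectra(spectra)
    wavelengths = spectra[0].wavelengths
    seed_ids = sorted(by_seed)
    rows = []
    if kind in ("ventral", "reverse"):
        for sid in seed_ids:
            s = by_seed[sid][kind]
            rows.append((s.reflectance, {"seed_id": sid, "side": kind, "label": s.label, "role": s.role}))
    elif kind == "mean":
        for sid in seed_ids:
            v, r = by_seed[sid]["ventral"], by_seed[sid]["reverse"]
            if v.label != r.label or v.role != r.role:
                raise ValueError(f"seed {sid} has inconsistent label/role across sides")
            rows.append((
                (v.reflectance + r.reflectance) / 2.0,
                {"seed_id": sid, "side": "mean", "label": v.label, "role": v.role},
            ))
    elif kind == "mixture":
        for sid in seed_ids:
            for side in ("ventral", "reverse"):
                s = by_seed[sid][side]
                if s.role == "calibration":
                    rows.append((s.reflectance, {"seed_id": sid, "side": side, "label": s.label, "role": s.role}))
        pred_ids = [sid for sid in seed_ids if by_seed[sid]["ventral"].role == "prediction"]
        if mixture_config == "both-sides":
            # keep every prediction row; a proportion config can be applied later
            take = [(sid, side) for sid in pred_ids for side in ("ventral", "reverse")]
        else:
            config = MixtureConfig() if mixture_config is None else mixture_config
            ventral_ids, reverse_ids = _partition_prediction_seeds(
                pred_ids, [by_seed[sid]["ventral"].label for sid in pred_ids], config
            )
            take = [(sid, "ventral") for sid in sorted(ventral_ids)]
            take += [(sid, "reverse") for sid in sorted(reverse_ids)]
        for sid, side in take:
            s = by_seed[sid][side]
            rows.append((s.reflectance, {"seed_id": sid, "side": side, "label": s.label, "role": s.role}))
    else:
        raise ValueError(f"unknown dataset kind {kind!r}")
    ds = _assemble(kind, rows, wavelengths)
    _check_no_leakage(ds)
    return ds


def _stratified_take(n_take: int, group_sizes: list[int]) -> list[int]:
    """Largest-remainder apportionment of ``n_take`` across groups."""
    total = sum(group_sizes)
    if n_take > total:
        raise ValueError(f"cannot take {n_take} from {total} seeds")
    quotas = [n_take * g / total for g in group_sizes]
    take = [int(q) for q in quotas]
    remainders = np.array(quotas) - np.array(take)
    for i in np.argsort(-remainders, kind="stable")[: n_take - sum(take)]:
        take[int(i)] += 1
    return take


def _partition_prediction_seeds(
    pred_ids: list[str], labels: list[int], config: MixtureConfig
) -> tuple[list[str], list[str]]:
    """Split prediction seeds into disjoint ventral- and reverse-contributing
    subsets, stratified by class so recall/precision stay comparable."""
    n_v, n_r = config.n_pred_ventral, config.n_pred_reverse
    if n_v + n_r > len(pred_ids):
        raise ValueError(
            f"infeasible mixture config: {n_v} + {n_r} > {len(pred_ids)} prediction seeds"
        )
    rng = np.random.default_rng(config.assignment_seed)
    groups = {}
    for lab in (VIABLE, NONVIABLE):
        ids = [sid for sid, l in zip(pred_ids, labels) if l == lab]
        rng.shuffle(ids)
        groups[lab] = ids
    sizes = [len(groups[VIABLE]), len(groups[NONVIABLE])]
    take_v = _stratified_take(n_v, sizes)
    remaining = [sizes[0] - take_v[0], sizes[1] - take_v[1]]
    if n_r > sum(remaining):
        raise ValueError("infeasible mixture config after stratified ventral draw")
    take_r = _stratified_take(n_r, remaining)
    ventral_ids, reverse_ids = [], []
    for gi, lab in enumerate((VIABLE, NONVIABLE)):
        ids = groups[lab]
        ventral_ids += ids[: take_v[gi]]
        reverse_ids += ids[take_v[gi]: take_v[gi] + take_r[gi]]
    return ventral_ids, reverse_ids


def apply_mixture_config(dataset: SpectralDataset, config: MixtureConfig) -> SpectralDataset:
    """Re-draw the prediction rows of a mixture dataset per ``config``.

    Requires the per-row provenance carried in ``dataset.meta``; prediction
    seeds are partitioned into disjoint side-contributing subsets and seeds
    beyond ``n_pred_ventral + n_pred_reverse`` are excluded.
    """
    if dataset.kind != "mixture":
        raise ValueError("apply_mixture_config expects a mixture dataset")
    meta = dataset.meta.reset_index(drop=True)
    is_pred = dataset.is_pred
    pred_meta = meta[is_pred]
    pred_ids = sorted(pred_meta["seed_id"].unique())
    label_of = {sid: int(dataset.y[is_pred][pred_meta["seed_id"].to_numpy() == sid][0]) for sid in pred_ids}
    ventral_ids, reverse_ids = _partition_prediction_seeds(
        pred_ids, [label_of[sid] for sid in pred_ids], config
    )
    available = set(zip(meta.loc[is_pred, "seed_id"], meta.loc[is_pred, "side"]))
    wanted = [(sid, "ventral") for sid in ventral_ids] + [(sid, "reverse") for sid in reverse_ids]
    missing = [w for w in wanted if w not in available]
    if missing:
        raise ValueError(
            f"prediction rows missing for {missing[:3]}...; build the mixture dataset "
            "with mixture_config='both-sides' before applying a proportion config"
        )
    keep = dataset.is_cal.copy()
    side = meta["side"].to_numpy()
    sid_arr = meta["seed_id"].to_numpy()
    keep |= is_pred & (
        (np.isin(sid_arr, ventral_ids) & (side == "ventral"))
        | (np.isin(sid_arr, reverse_ids) & (side == "reverse"))
    )
    out = SpectralDataset(
        kind="mixture", X=dataset.X[keep], y=dataset.y[keep],
        roles=dataset.roles[keep], wavelengths=dataset.wavelengths,
        meta=meta[keep].reset_index(drop=True),
    )
    _check_no_leakage(out)
    return out


def _check_no_leakage(ds: SpectralDataset) -> None:
    cal = set(ds.meta.loc[np.asarray(ds.is_cal), "seed_id"])
    pred = set(ds.meta.loc[np.asarray(ds.is_pred), "seed_id"])
    overlap = cal & pred
    if overlap:
        raise AssertionError(f"calibration seeds leaked into prediction: {sorted(overlap)[:5]}")


def split_roles(
    seed_ids: list[str],
    labels: list[int],
    counts: dict[str, int] | None = None,
    rng_seed: int = 0,
) -> dict[str, str]:
    """Stratified random calibration/prediction assignment.

    ``counts`` keys: cal_viable, cal_nonviable, pred_viable, pred_nonviable
    (defaults 75/31/38/16). The per-class totals must match the population
    exactly.
    """
    counts = counts or {"cal_viable": 75, "cal_nonviable": 31, "pred_viable": 38, "pred_nonviable": 16}
    rng = np.random.default_rng(rng_seed)
    assignment: dict[str, str] = {}
    for lab, cal_key, pred_key in ((VIABLE, "cal_viable", "pred_viable"), (NONVIABLE, "cal_nonviable", "pred_nonviable")):
        ids = [sid for sid, l in zip(seed_ids, labels) if l == lab]
        want = counts[cal_key] + counts[pred_key]
        if len(ids) != want:
            raise ValueError(
                f"class {lab} has {len(ids)} seeds but counts request {want}"
            )
        ids = list(ids)
        rng.shuffle(ids)
        for sid in ids[: counts[cal_key]]:
            assignment[sid] = "calibration"
        for sid in ids[counts[cal_key]:]:
            assignment[sid] = "prediction"
    return assignment
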