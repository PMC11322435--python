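"""Exhaustive instance-level retrieval evaluation and the replacement grid.

The metric is top-k retrieval success (Acc@k): the fraction of queries
whose single correct counterpart appears among the first k retrieved
repository images.  Every image of the query modality is used as a query
(exhaustive evaluation); a query whose counterpart is missing from the
ranking is assigned the finite sentinel rank ``len(repo) + 1``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bow import RetrievalIndex
from .features import ExtractorConfig

logger = logging.getLogger(__name__)

__all__ = ["EvalResult", "acc_at_k", "evaluate_direction", "run_replacement_grid"]

DEFAULT_KS = (1, 5, 10, 15)


@dataclass
class EvalResult:
    """Per-query correct-match ranks plus Acc@k for the configured k set."""

    n_queries: int
    ranks: Dict[str, int]
    acc: Dict[int, float]
    descriptor: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "ranks": self.ranks,
            "acc": {str(k): v for k, v in self.acc.items()},
            "descriptor": self.descriptor,
        }


def acc_at_k(ranks: Sequence[float], k: int) -> float:
    """Fraction of correct-match ranks that are <= k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranks = list(ranks)
    if not ranks:
        raise ValueError("ranks must be nonempty")
    return sum(1 for r in ranks if r <= k) / len(ranks)


def evaluate_direction(
    queries: Sequence[Tuple[str, object]],
    index: RetrievalIndex,
    pair_of: Dict[str, str],
    *,
    ks: Sequence[int] = DEFAULT_KS,
    rerank_top_k: Optional[int] = None,
    rerank_mode: str = "patch",
    rerank_patch_stride: Optional[int] = None,
    tile_patch_px: Optional[int] = None,
    descriptor: Optional[dict] = None,
) -> EvalResult:
    """Run every query against a built index and record correct-match ranks.

    ``queries`` are (query id, image) pairs; ``pair_of`` maps each query id
    to its single correct repository id.  Missing counterparts are a
    validation error; a counterpart absent from a ranking gets the
    sentinel rank ``len(repo) + 1``.
    """
    index._require_built()
    repo_ids = set(index.ids)
    missing = [qid for qid, _ in queries if pair_of.get(qid) not in repo_ids]
    if missing:
        raise ValueError(
            f"queries without a repository counterpart: {sorted(missing)}"
        )
    sentinel = len(index.ids) + 1
    ranks: Dict[str, int] = {}
    for qid, img in queries:
        ranked = index.retrieve(img, tile_patch_px=tile_patch_px)
        if rerank_top_k is not None:
            ranked = index.rerank(
                img, ranked, top_k=rerank_top_k, mode=rerank_mode,
                patch_stride=rerank_patch_stride,
            )
        rank = ranked.rank_of(pair_of[qid])
        ranks[qid] = sentinel if rank is None else rank
        logger.debug("query %s -> rank %d", qid, ranks[qid])
    rank_values = list(ranks.values())
    acc = {int(k): acc_at_k(rank_values, int(k)) for k in ks}
    return EvalResult(
        n_queries=len(queries),
        ranks=ranks,
        acc=acc,
        descriptor=dict(descriptor or {}),
    )


def run_replacement_grid(
    images: Dict[str, Dict[str, object]],
    *,
    representations: Sequence[str] = ("raw", "comir"),
    extractors: Sequence[str] = ("surf_like", "sift_like"),
    query_types: Sequence[str] = ("full", "patch"),
    transforms: Sequence[str] = ("none", "rigid"),
    reranks: Sequence[object] = ("none", 15, 30),
    modalities: Tuple[str, str] = ("A", "B"),
    encoder_pair=None,
    patch_px: int = 256,
    vocab_size: int = 512,
    seed: int = 0,
    ks: Sequence[int] = DEFAULT_KS,
    grid_spacing: Tuple[int, int] = (16, 16),
    scales: Tuple[int, ...] = (32, 64),
    out_csv=None,
    out_json=None,
) -> pd.DataFrame:
    """Evaluate every grid cell in both retrieval directions.

    ``images`` maps a view name to ``{pair_id: image}`` dictionaries; the
    required views are ``"A"``/``"B"`` (untransformed) and, when the grid
    includes rigid transforms, ``"A_T"``/``"B_T"``.  When ``"comir"`` is in
    the representation axis, ``encoder_pair`` must supply trained encoders
    and the corresponding representation views are computed on the fly.
    One row per (cell, direction), in the within/cross-modality x
    with/without-transform layout.
    """
    from .comir import compute_representation  # local import to avoid cycle

    for rep in representations:
        if rep not in ("raw", "comir"):
            raise ValueError(f"invalid representation {rep!r}")
        if rep == "comir" and encoder_pair is None:
            raise ValueError("comir representation requested without encoder_pair")
    for rr in reranks:
        if rr not in ("none", 15, 30):
            raise ValueError(f"invalid rerank setting {rr!r}")

    mod_a, mod_b = modalities

    def view(rep: str, mod_key: str) -> Dict[str, object]:
        base = images[mod_key]
        if rep == "raw":
            return base
        cache_key = ("comir", mod_key)
        if cache_key not in _view_cache:
            modality = mod_key.split("_")[0]
            enc = encoder_pair.for_modality(modality)
            _view_cache[cache_key] = {
                pid: compute_representation(enc, img) for pid, img in base.items()
            }
        return _view_cache[cache_key]

    _view_cache: Dict[Tuple, Dict[str, object]] = {}
    rows = []
    results = []
    for rep in representations:
        for ext in extractors:
            cfg = ExtractorConfig(kind=ext, grid_spacing=grid_spacing, scales=scales)
            for direction in ((mod_a, mod_b), (mod_b, mod_a)):
                q_mod, r_mod = direction
                repo_view = view(rep, r_mod)
                index = RetrievalIndex(
                    extractor=cfg, vocab_size=vocab_size, seed=seed
                ).build(
                    [_Named(pid, img) for pid, img in sorted(repo_view.items())]
                )
                for q_type in query_types:
                    for transform in transforms:
                        q_key = q_mod if transform == "none" else f"{q_mod}_T"
                        if q_key not in images:
                            raise ValueError(
                                f"grid requires image view {q_key!r}"
                            )
                        q_view = view(rep, q_key)
                        q_items = []
                        for pid, img in sorted(q_view.items()):
                            if q_type == "patch":
                                img = _center_patch(img, patch_px, pid)
                            q_items.append((pid, img))
                        for rr in reranks:
                            res = evaluate_direction(
                                q_items,
                                index,
                                {pid: pid for pid, _ in q_items},
                                ks=ks,
                                rerank_top_k=None if rr == "none" else int(rr),
                                rerank_mode="patch" if q_type == "patch" else "full_image",
                                descriptor={
                                    "representation": rep,
                                    "extractor": ext,
                                    "query": q_type,
                                    "transform": transform,
                                    "rerank": rr,
                                    "direction": f"{q_mod}2{r_mod}",
                                },
                            )
                            results.append(res)
                            row = dict(res.descriptor)
                            row["n_queries"] = res.n_queries
                            for k in ks:
                                row[f"acc@{k}"] = res.acc[int(k)]
                            rows.append(row)
    table = pd.DataFrame(rows)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_csv, index=False)
    if out_json is not None:
        Path(out_json).parent.mkdir(parents=True, exist_ok=True)
        with open(out_json, "w") as fh:
            json.dump([r.to_dict() for r in results], fh, indent=1)
    return table


class _Named:
    def __init__(self, image_id: str, img) -> None:
        self.id = image_id
        self._img = img

    def gray(self):
        return self._img.gray() if hasattr(self._img, "gray") else np.asarray(self._img)


def _center_patch(img, patch_px: int, pid: str):
    gray = img.gray() if hasattr(img, "gray") else np.asarray(img)
    h, w = gray.shape[:2]
    r0 = (h - patch_px) // 2
    c0 = (w - patch_px) // 2
    return _Named(pid, gray[r0 : r0 + patch_px, c0 : c0 + patch_px])
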