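"""End-to-end experiments at desk scale.

Two studies are packaged here so that the test suite, the command line
and the reproduction script all run the identical code path:

* :func:`run_verification_experiment` — train a two-layer network to
  mark blob boundary superpixels at orientation theta = 0, then compare
  the *rotated* network Phi_theta against the unrotated Phi_0 on data
  whose target orientation is theta.  If filter rotation works, the
  rotated network must show the smaller MSE on every split.

* :func:`run_detection_experiment` — train the four-layer architecture
  to regress W-scaled target masks on synthetic ear scenes, evaluate
  argmax-node detection accuracy on a person-disjoint test split, and
  evaluate the rotation bank (max-response and any-response rules) on
  rotated copies of the test scenes.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph import GraphBuildConfig, build_graph
from .oriented import make_verification_dataset, retarget
from .synth import Scene, gen_blob_mask, gen_dataset, scenes_by_split
from .train import (TrainConfig, accuracy, build_architecture, detect,
                    ensemble_detect_any, ensemble_detect_max, evaluate_hit,
                    mean_mse, train)
from .transforms import rotate_network, rotation_bank

VERIFICATION_EVAL_ANGLES = (3 * np.pi / 4, -np.pi / 2)


def run_verification_experiment(
    seed: int = 0,
    n_masks: int = 100,
    mask_size: Tuple[int, int] = (96, 128),
    epochs: int = 2000,
    learning_rate: float = 1e-3,
    eval_interval: int = 50,
    eval_angles: Sequence[float] = VERIFICATION_EVAL_ANGLES,
) -> dict:
    """Oriented-edge experiment; returns MSE tables and the trained model.

    The returned dict has ``mse[theta_label][model][split]`` where model
    is ``"phi0"`` or ``"phi_theta"``; at theta = 0 the two coincide.
    """
    masks = [gen_blob_mask(int(s), mask_size)
             for s in np.random.SeedSequence(seed).generate_state(n_masks) % (2 ** 31)]
    data0 = make_verification_dataset(masks, theta=0.0)
    net = build_architecture("verification", seed=seed)
    cfg = TrainConfig(learning_rate=learning_rate, epochs=epochs,
                      eval_interval=eval_interval, seed=seed)
    best, history = train(net, data0["train"], data0["val"], cfg)

    mse: Dict[str, Dict[str, Dict[str, float]]] = {}
    for theta in [0.0, *eval_angles]:
        label = f"{theta:+.6f}"
        data_t = {split: retarget(graphs, theta) for split, graphs in data0.items()}
        net_t = rotate_network(best, theta)
        mse[label] = {
            "phi0": {s: mean_mse(best, g) for s, g in data_t.items()},
            "phi_theta": {s: mean_mse(net_t, g) for s, g in data_t.items()},
        }
    return {"mse": mse, "model": best, "history": history,
            "eval_angles": list(eval_angles)}


def _detection_graphs(scenes: Sequence[Scene], config: GraphBuildConfig):
    graphs = []
    for sc in scenes:
        g = build_graph(sc.image, mask=sc.mask, config=config)
        graphs.append((g, sc.bbox))
    return graphs


def _rotated_scenes(subject_ids, scenes_per_subject, rotation_range, seed, size):
    """Fresh scenes for given subjects with rotations drawn from ``rotation_range``."""
    from .synth import BACKGROUND_TEXTURES, SceneSpec, gen_scene

    lo, hi = rotation_range
    out = []
    for sid in subject_ids:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4, sid)))
        for i in range(scenes_per_subject):
            spec = SceneSpec(
                seed=seed, size=size, rotation=float(rng.uniform(lo, hi)),
                illumination=float(rng.uniform(0.85, 1.15)),
                background_texture=BACKGROUND_TEXTURES[i % len(BACKGROUND_TEXTURES)],
                subject_id=sid, scene_id=100 + i)
            out.append(gen_scene(spec))
    return out


def run_detection_experiment(
    seed: int = 0,
    n_subjects: int = 38,
    scenes_per_subject: int = 4,
    size: Tuple[int, int] = (96, 128),
    area: float = 256.0,
    hops: int = 2,
    target_scale: float = 100.0,
    epochs: int = 200,
    learning_rate: float = 1e-4,
    eval_interval: int = 50,
    bank_count: int = 11,
    rotated_rotation_range: Tuple[float, float] = (-np.pi, np.pi),
) -> dict:
    """Synthetic ear-detection study; returns accuracies and the trained model.

    Keys of the result: ``accuracy`` maps split name to argmax-detection
    accuracy of the selected network on upright scenes;
    ``rotated_accuracy`` holds ``phi0`` / ``max`` / ``any`` rule
    accuracies of the rotation bank on in-plane rotated test scenes.
    """
    config = GraphBuildConfig(area=area, hops=hops, target_scale=target_scale,
                              downscale=1.0)
    scenes, split = gen_dataset(n_subjects, scenes_per_subject,
                                rotation_range=(0.0, 0.0), seed=seed, size=size)
    by_split = scenes_by_split(scenes, split)
    graphs = {name: _detection_graphs(sc, config) for name, sc in by_split.items()}

    net = build_architecture("main", seed=seed)
    cfg = TrainConfig(learning_rate=learning_rate, epochs=epochs,
                      eval_interval=eval_interval, seed=seed)
    best, history = train(net, [g for g, _ in graphs["train"]],
                          [g for g, _ in graphs["val"]], cfg)

    enlargement = float(np.sqrt(area))
    acc = {}
    for name, items in graphs.items():
        hits = []
        for g, bbox in items:
            res = detect(best.forward(g)[:, 0], g.centroids)
            hits.append(evaluate_hit(res, bbox, enlargement))
        acc[name] = accuracy(hits)

    # rotated test scenes: the same unseen subjects (same appearance),
    # new in-plane rotations and illumination
    rot_scenes = _rotated_scenes(split["test"], scenes_per_subject,
                                 rotated_rotation_range, seed, size)
    rot_graphs = _detection_graphs(rot_scenes, config)
    bank = rotation_bank(best, count=bank_count)
    hits_phi0, hits_max, hits_any = [], [], []
    for g, bbox in rot_graphs:
        res0 = detect(best.forward(g)[:, 0], g.centroids)
        hits_phi0.append(evaluate_hit(res0, bbox, enlargement))
        resm = ensemble_detect_max(bank, g)
        hits_max.append(evaluate_hit(resm, bbox, enlargement))
        hits_any.append(ensemble_detect_any(bank, g, bbox, enlargement))
    rotated = {"phi0": accuracy(hits_phi0), "max": accuracy(hits_max),
               "any": accuracy(hits_any)}
    counts = {name: len(items) for name, items in graphs.items()}
    counts["rotated_test"] = len(rot_graphs)
    return {"accuracy": acc, "rotated_accuracy": rotated, "model": best,
            "history": history, "counts": counts, "split": split}
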