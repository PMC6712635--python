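"""Trained-state persistence: a JSON manifest plus a binary array sidecar.

Scalars and structure go into ``state.json``; every numpy array is stored in
``arrays.npz`` and referenced from the JSON by key, so saved states remain
inspectable while arrays keep full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .base import FrequencyDecoder, make_decoder
from .cfa import CFADecoder
from .l1mcca import L1MccaDecoder, L1MccaFreqState
from .mlr import MLRDecoder
from .msetcca import MsetCCADecoder, MsetFreqState

__all__ = ["save_decoder_state", "load_decoder_state"]


def _hyperparams(dec: FrequencyDecoder) -> dict:
    hp = {}
    for key in ("n_harmonics", "reference_shape", "lam", "lams", "standardize",
                "n_common", "k_neighbors", "seed"):
        if hasattr(dec, key):
            val = getattr(dec, key)
            hp[key] = list(val) if isinstance(val, tuple) else val
    return hp


def save_decoder_state(dec: FrequencyDecoder, out_dir: str | Path) -> Path:
    """Write a fitted (or training-free) decoder to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    manifest: dict = {
        "decoder": dec.name,
        "freqs_hz": list(dec.freqs_hz),
        "fs": dec.fs,
        "fitted": dec.fitted_,
        "hyperparams": _hyperparams(dec),
    }

    def put(key: str, arr: np.ndarray) -> str:
        arrays[key] = np.asarray(arr)
        return key

    if isinstance(dec, L1MccaDecoder) and dec.fitted_:
        manifest["states"] = {
            str(f): {
                "w1": put(f"l1mcca_w1_{i}", st.w1),
                "w3": put(f"l1mcca_w3_{i}", st.w3),
                "v": put(f"l1mcca_v_{i}", st.v),
                "optimized_reference": put(f"l1mcca_ref_{i}", st.optimized_reference),
                "objective": st.objective,
                "n_sweeps": st.n_sweeps,
            }
            for i, (f, st) in enumerate(dec.states_.items())
        }
    elif isinstance(dec, MsetCCADecoder) and dec.fitted_:
        manifest["states"] = {
            str(f): {
                "filters": put(f"mset_filters_{i}", st.filters),
                "reference": put(f"mset_ref_{i}", st.reference),
                "rho": st.rho,
            }
            for i, (f, st) in enumerate(dec.states_.items())
        }
    elif isinstance(dec, CFADecoder) and dec.fitted_:
        manifest["bases"] = {
            str(f): put(f"cfa_basis_{i}", b) for i, (f, b) in enumerate(dec.bases_.items())
        }
    elif isinstance(dec, MLRDecoder) and dec.fitted_:
        manifest["mlr"] = {
            "W": put("mlr_W", dec.W_),
            "train_mean": put("mlr_mean", dec.train_mean_),
            "train_features": put("mlr_feat", dec.train_features_),
            "train_labels": put("mlr_labels", dec.train_labels_),
        }

    (out / "state.json").write_text(json.dumps(manifest, indent=2))
    np.savez(out / "arrays.npz", **arrays)
    return out


def load_decoder_state(in_dir: str | Path) -> FrequencyDecoder:
    """Rebuild a decoder saved by :func:`save_decoder_state`."""
    root = Path(in_dir)
    manifest = json.loads((root / "state.json").read_text())
    with np.load(root / "arrays.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    hp = dict(manifest["hyperparams"])
    if "lams" in hp and hp["lams"] is not None:
        hp["lams"] = tuple(hp["lams"])
    dec = make_decoder(manifest["decoder"], manifest["freqs_hz"], manifest["fs"], **hp)
    if not manifest["fitted"]:
        return dec
    if isinstance(dec, L1MccaDecoder):
        dec.states_ = {
            float(f): L1MccaFreqState(
                w1=arrays[st["w1"]],
                w3=arrays[st["w3"]],
                v=arrays[st["v"]],
                optimized_reference=arrays[st["optimized_reference"]],
                objective=st["objective"],
                n_sweeps=st["n_sweeps"],
            )
            for f, st in manifest["states"].items()
        }
    elif isinstance(dec, MsetCCADecoder):
        dec.states_ = {
            float(f): MsetFreqState(
                filters=arrays[st["filters"]],
                reference=arrays[st["reference"]],
                rho=st["rho"],
            )
            for f, st in manifest["states"].items()
        }
    elif isinstance(dec, CFADecoder):
        dec.bases_ = {float(f): arrays[k] for f, k in manifest["bases"].items()}
    elif isinstance(dec, MLRDecoder):
        dec.W_ = arrays[manifest["mlr"]["W"]]
        dec.train_mean_ = arrays[manifest["mlr"]["train_mean"]]
        dec.train_features_ = arrays[manifest["mlr"]["train_features"]]
        dec.train_labels_ = arrays[manifest["mlr"]["train_labels"]]
    dec.fitted_ = True
    return dec
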