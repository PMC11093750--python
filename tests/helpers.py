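"""Shared test helpers: an analytic stand-in for the steering network.

The stand-in computes steering and membrane distance from patch content
alone (bright-centroid parabola fitting plus a lumen-confidence heuristic)
and emulates Monte-Carlo-dropout spread whose amplitude shrinks with that
confidence.  It exercises the full inference machinery — patch extraction,
MC sampling, uncertainty scoring, direction selection, tracing, validation
— without requiring a trained model.
"""

import numpy as np
from scipy.ndimage import uniform_filter
from types import SimpleNamespace


class LumenStandIn:
    def __init__(self, shape=(24, 24, 8), anchor=3, p=0.4, z_spacing=0.09):
        self.cfg = SimpleNamespace(input_shape=shape, dropout_rate=0.5,
                                   output_scale=1.0)
        self.shape = shape
        self.anchor = anchor
        self.p = p
        self.z_spacing = z_spacing

    def conv_features(self, x, cache=False):
        return np.asarray(x, dtype=np.float32).reshape(len(x), -1)

    def head_forward(self, h, cache=False):
        A, B, C = self.shape
        out = np.empty((len(h), 3), dtype=np.float32)
        a_off = (np.arange(A) - (A - 1) / 2) * (self.p / A)
        for m in range(len(h)):
            raw = h[m].reshape(A, B, C)
            patch = uniform_filter(raw, size=(5, 5, 1))
            ctr = raw[A//2-4:A//2+4, B//2-4:B//2+4, -2:]
            conf = float(np.clip(np.clip(ctr, 0, None).mean() / 0.3, 0.0, 1.0))
            # average bright centroid over ahead planes, distance-weighted
            num = np.zeros(2)
            den = 0.0
            dz_mean = 0.0
            for c in range(self.anchor + 1, C):
                plane = np.clip(patch[:, :, c], 0, None)
                w = float(plane.sum())
                if w < 1e-6:
                    continue
                da = float((a_off[:, None] * plane).sum() / w)
                db = float((a_off[None, :] * plane).sum() / w)
                num += (da, db)
                den += 1.0
                dz_mean += (c - self.anchor) * self.z_spacing
            if den == 0:
                k = np.zeros(2)
            else:
                off = num / den
                dz = dz_mean / den
                k = 2.0 * off / dz**2
            # clamp the deterministic magnitude into a sane steering band
            mag = float(np.linalg.norm(k))
            if mag > 1e-9:
                k = k * (np.clip(mag, 0.5, 1.0) / mag)
            else:
                k = np.array([0.5, 0.0])
            # low confidence -> mask-driven instability (zero-mean Rademacher
            # signs derived from the dropout pattern)
            zeros = (raw == 0.0)
            s1 = 1.0 if int(zeros[: A // 2].sum()) % 2 == 0 else -1.0
            s2 = 1.0 if int(zeros[:, : B // 2].sum()) % 2 == 0 else -1.0
            alpha = 3.0 * (1.0 - conf) ** 2
            k = k + alpha * np.array([s1, s2])
            dm = (C - 1 - self.anchor) * self.z_spacing
            for c in range(self.anchor, C):
                if patch[A//2-1:A//2+2, B//2-1:B//2+2, c].mean() < -0.3:
                    dm = (c - self.anchor) * self.z_spacing
                    break
            out[m] = (k[0], k[1], dm)
        return out


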