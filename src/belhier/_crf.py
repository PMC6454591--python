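"""Linear-chain conditional random field trained with L-BFGS.

Minimal deterministic engine behind the hierarchical labeler: string
features per token, emission weights per (feature, label), transition and
start weights, L2 penalty (coefficient ``c2``), exact forward-backward
gradients, Viterbi decoding.  Everything is initialized at zero and
optimized with scipy's L-BFGS-B, so training is reproducible bit-for-bit
given the same corpus order.
"""

from __future__ import annotations

import json

import numpy as np
from scipy.optimize import minimize


def _logsumexp_rows(m: np.ndarray) -> np.ndarray:
    """logsumexp over axis 0 of a (K, K) matrix, per column."""
    mx = m.max(axis=0)
    return mx + np.log(np.exp(m - mx).sum(axis=0))


def _logsumexp_cols(m: np.ndarray) -> np.ndarray:
    mx = m.max(axis=1)
    return mx + np.log(np.exp(m - mx[:, None]).sum(axis=1))


class ChainCRF:
    """First-order linear-chain CRF over string-feature sequences."""

    def __init__(self, c2: float = 1.0, max_iter: int = 100, gtol: float = 1e-5):
        self.c2 = c2
        self.max_iter = max_iter
        self.gtol = gtol
        self.labels_: list[str] = []
        self.features_: list[str] = []
        self._feat_index: dict[str, int] = {}
        self.w_emit: np.ndarray | None = None  # (F, K)
        self.w_trans: np.ndarray | None = None  # (K, K)
        self.w_start: np.ndarray | None = None  # (K,)

    # -- encoding -----------------------------------------------------------

    def _encode(self, X: list[list[list[str]]], train: bool):
        """Pack all tokens into one padded feature-id matrix plus seq slices."""
        if train:
            feats = sorted({f for seq in X for tok in seq for f in tok})
            self.features_ = feats
            self._feat_index = {f: i for i, f in enumerate(feats)}
        F = len(self.features_)
        idx = self._feat_index
        rows: list[list[int]] = []
        slices: list[tuple[int, int]] = []
        for seq in X:
            start = len(rows)
            for tok in seq:
                rows.append(sorted(idx[f] for f in tok if f in idx))
            slices.append((start, len(rows)))
        fmax = max((len(r) for r in rows), default=1) or 1
        mat = np.full((len(rows), fmax), F, dtype=np.int64)  # F = dummy pad id
        for i, r in enumerate(rows):
            mat[i, : len(r)] = r
        return mat, slices

    def _emissions(self, mat: np.ndarray, w_emit: np.ndarray) -> np.ndarray:
        K = w_emit.shape[1]
        ext = np.vstack([w_emit, np.zeros((1, K))])
        return ext[mat].sum(axis=1)

    # -- training -----------------------------------------------------------

    def fit(self, X: list[list[list[str]]], y: list[list[str]]) -> "ChainCRF":
        if not X:
            raise ValueError("empty training corpus")
        for seq, tags in zip(X, y):
            if len(seq) != len(tags):
                raise ValueError("feature/label length mismatch")
        self.labels_ = sorted({t for tags in y for t in tags})
        lab_index = {t: i for i, t in enumerate(self.labels_)}
        K = len(self.labels_)
        mat, slices = self._encode(X, train=True)
        F = len(self.features_)
        y_enc = [np.array([lab_index[t] for t in tags], dtype=np.int64) for tags in y]

        n_emit = F * K
        n_trans = K * K

        def objective(theta: np.ndarray):
            w_emit = theta[:n_emit].reshape(F, K)
            w_trans = theta[n_emit : n_emit + n_trans].reshape(K, K)
            w_start = theta[n_emit + n_trans :]
            E_all = self._emissions(mat, w_emit)
            nll = 0.0
            gE = np.zeros_like(E_all)
            gT = np.zeros((K, K))
            gS = np.zeros(K)
            for (a, b), ys in zip(slices, y_enc):
                T = b - a
                if T == 0:
                    continue
                E = E_all[a:b]
                alpha = np.empty((T, K))
                alpha[0] = w_start + E[0]
                for t in range(1, T):
                    alpha[t] = _logsumexp_rows(alpha[t - 1][:, None] + w_trans) + E[t]
                mx = alpha[-1].max()
                logZ = mx + np.log(np.exp(alpha[-1] - mx).sum())
                beta = np.empty((T, K))
                beta[-1] = 0.0
                for t in range(T - 2, -1, -1):
                    beta[t] = _logsumexp_cols(w_trans + (E[t + 1] + beta[t + 1])[None, :])
                gamma = np.exp(alpha + beta - logZ)
                diff = gamma.copy()
                diff[np.arange(T), ys] -= 1.0
                gE[a:b] = diff
                for t in range(1, T):
                    xi = np.exp(
                        alpha[t - 1][:, None] + w_trans + (E[t] + beta[t])[None, :] - logZ
                    )
                    gT += xi
                    gT[ys[t - 1], ys[t]] -= 1.0
                gS += gamma[0]
                gS[ys[0]] -= 1.0
                gold = w_start[ys[0]] + E[np.arange(T), ys].sum()
                if T > 1:
                    gold += w_trans[ys[:-1], ys[1:]].sum()
                nll += logZ - gold
            gWx = np.zeros((F + 1, K))
            np.add.at(gWx, mat, gE[:, None, :])
            grad = np.concatenate([gWx[:F].ravel(), gT.ravel(), gS])
            nll += self.c2 * float(theta @ theta)
            grad += 2.0 * self.c2 * theta
            return nll, grad

        theta0 = np.zeros(n_emit + n_trans + K)
        result = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter, "gtol": self.gtol, "ftol": 1e-9},
        )
        theta = result.x
        self.w_emit = theta[:n_emit].reshape(F, K)
        self.w_trans = theta[n_emit : n_emit + n_trans].reshape(K, K)
        self.w_start = theta[n_emit + n_trans :]
        return self

    # -- decoding -----------------------------------------------------------

    def predict(self, X: list[list[list[str]]]) -> list[list[str]]:
        if self.w_emit is None:
            raise RuntimeError("model is not trained")
        mat, slices = self._encode(X, train=False)
        E_all = self._emissions(mat, self.w_emit)
        K = len(self.labels_)
        out: list[list[str]] = []
        for a, b in slices:
            T = b - a
            if T == 0:
                out.append([])
                continue
            E = E_all[a:b]
            delta = np.empty((T, K))
            back = np.zeros((T, K), dtype=np.int64)
            delta[0] = self.w_start + E[0]
            for t in range(1, T):
                scores = delta[t - 1][:, None] + self.w_trans
                back[t] = scores.argmax(axis=0)
                delta[t] = scores[back[t], np.arange(K)] + E[t]
            path = [int(delta[-1].argmax())]
            for t in range(T - 1, 0, -1):
                path.append(int(back[t, path[-1]]))
            path.reverse()
            out.append([self.labels_[i] for i in path])
        return out

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "c2": self.c2,
            "labels": self.labels_,
            "features": self.features_,
            "w_emit": self.w_emit.tolist(),
            "w_trans": self.w_trans.tolist(),
            "w_start": self.w_start.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChainCRF":
        crf = cls(c2=d["c2"])
        crf.labels_ = list(d["labels"])
        crf.features_ = list(d["features"])
        crf._feat_index = {f: i for i, f in enumerate(crf.features_)}
        crf.w_emit = np.asarray(d["w_emit"], dtype=float)
        crf.w_trans = np.asarray(d["w_trans"], dtype=float)
        crf.w_start = np.asarray(d["w_start"], dtype=float)
        return crf

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ChainCRF":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
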