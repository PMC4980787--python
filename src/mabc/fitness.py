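"""Subset fitness: LOOCV SVM accuracy combined with parsimony.

A candidate gene subset (binary mask) is scored by leave-one-out
cross-validation of a support vector machine trained on the selected
columns, then folded into a scalar

    fitness = w1 * accuracy + (1 - w1) * (n - ns) / n

where ``accuracy`` is the LOOCV accuracy as a fraction, ``n`` the total
gene count after prefiltering, and ``ns`` the number of selected genes.
Fitness therefore lives in [0, 1], rising with accuracy and falling with
subset size.

Evaluation is fully deterministic: the same mask always yields the same
accuracy, so results are memoized by mask bit-pattern.  Two SVM backends
are provided: the default drives scikit-learn's bundled libsvm bindings
directly and skips refitting any fold whose held-out sample is not a
support vector of the full fit (removing an inactive constraint leaves the
solution unchanged, and a non-support sample is classified correctly by
every pairwise decision function, so its vote cannot flip) — an exact
shortcut; the portable backend runs an explicit fold loop through
:class:`sklearn.svm.SVC`.
"""

from __future__ import annotations

import numpy as np

try:  # fast path: libsvm Cython bindings shipped inside scikit-learn
    from sklearn.svm import _libsvm as _lib

    _lib.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except Exception:  # pragma: no cover - depends on sklearn internals
    _lib = None
    _HAVE_LIBSVM = False

from sklearn.svm import SVC

__all__ = ["FitnessEvaluator"]


class FitnessEvaluator:
    """LOOCV-SVM fitness of gene masks over a (prefiltered) dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
        Samples x genes matrix the masks index into.
    w1 : float
        Accuracy/parsimony tradeoff in [0, 1]; higher favors accuracy.
    kernel : {'linear', 'rbf'}
        SVM kernel.  ``gamma`` is ignored by the linear kernel.
    C, gamma : float
        SVM penalty and RBF width.
    max_iter : int
        Per-fit cap on libsvm solver iterations.  With a large ``C`` the
        solver can need >10^5 iterations on subsets that do not separate
        the classes; the cap bounds that cost while leaving separable
        (informative) subsets, which converge in a few hundred iterations,
        untouched.  Set to -1 for the uncapped solver.
    backend : {'auto', 'libsvm', 'svc'}
        ``'libsvm'`` is the fast in-process path; ``'svc'`` the public
        scikit-learn estimator loop.  ``'auto'`` picks libsvm when present.
    """

    def __init__(self, dataset, w1=0.85, kernel="linear", C=2000.0,
                 gamma=1e-4, max_iter=2000, backend="auto"):
        if not 0.0 <= w1 <= 1.0:
            raise ValueError("w1 must lie in [0, 1]")
        if kernel not in ("linear", "rbf"):
            raise ValueError("kernel must be 'linear' or 'rbf'")
        self.dataset = dataset
        self.w1 = float(w1)
        self.kernel = kernel
        self.C = float(C)
        self.gamma = float(gamma)
        self.max_iter = int(max_iter)
        if backend == "auto":
            backend = "libsvm" if _HAVE_LIBSVM else "svc"
        if backend == "libsvm" and not _HAVE_LIBSVM:
            raise RuntimeError("libsvm backend unavailable in this scikit-learn build")
        self.backend = backend
        self._X = np.ascontiguousarray(dataset.values, dtype=np.float64)
        self._y = np.ascontiguousarray(dataset.labels, dtype=np.float64)
        self._n = dataset.n_genes
        self._N = dataset.n_samples
        self._n_classes = dataset.n_classes
        counts = dataset.class_sizes()
        # held-out samples from singleton classes can never be predicted
        # correctly; with two classes their fold cannot even be fitted
        self._singleton = {
            i for i in range(self._N) if counts[dataset.labels[i]] == 1
        }
        self._cache: dict = {}

    # -- public API --------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self._n

    def loocv_accuracy(self, mask) -> float:
        """LOOCV accuracy (fraction in [0, 1]) of the masked gene subset."""
        return self._evaluate(mask)[0]

    def fitness(self, mask) -> float:
        """Scalar fitness in [0, 1] of the masked gene subset."""
        return self._evaluate(mask)[1]

    def evaluate(self, mask):
        """(accuracy fraction, fitness) of the masked subset, memoized."""
        return self._evaluate(mask)

    @property
    def cache_size(self) -> int:
        return len(self._cache)

    # -- internals ---------------------------------------------------------

    def _evaluate(self, mask):
        bits = np.asarray(mask, dtype=np.uint8)
        if bits.shape != (self._n,):
            raise ValueError(f"mask must have length {self._n}")
        ns = int(bits.sum())
        if ns == 0:
            raise ValueError(
                "empty gene mask submitted for evaluation; the neighborhood "
                "operator must repair all-zero masks before scoring"
            )
        key = bits.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        cols = np.flatnonzero(bits)
        X = np.ascontiguousarray(self._X[:, cols])
        if self.backend == "libsvm":
            acc = self._loocv_libsvm(X)
        else:
            acc = self._loocv_svc(X)
        fit = self.w1 * acc + (1.0 - self.w1) * (self._n - ns) / self._n
        out = (acc, fit)
        self._cache[key] = out
        return out

    def _svm_kwargs(self):
        return dict(svm_type=0, kernel=self.kernel, C=self.C,
                    gamma=self.gamma, max_iter=self.max_iter)

    def _loocv_libsvm(self, X) -> float:
        y = self._y
        N = self._N
        kw = self._svm_kwargs()
        pkw = dict(svm_type=0, kernel=self.kernel, gamma=self.gamma)
        fast_linear = self.kernel == "linear" and self._n_classes == 2
        model = _lib.fit(X, y, **kw)
        if fast_linear:
            # binary linear decision reconstructed from the dual solution:
            # dec > 0 predicts the numerically smaller class label
            w = model[3][0] @ model[1]
            full_correct = ((X @ w + model[4][0] > 0) == (y == 0.0))
        else:
            full_correct = _lib.predict(X, *model[:7], **pkw) == y
        sv = set(model[0].tolist())
        correct = 0
        keep = np.ones(N, dtype=bool)
        for i in range(N):
            if i not in sv:
                correct += full_correct[i]
                continue
            if i in self._singleton:
                continue  # its class is absent from the training fold
            keep[i] = False
            mi = _lib.fit(np.ascontiguousarray(X[keep]), y[keep], **kw)
            if fast_linear:
                wi = mi[3][0] @ mi[1]
                correct += (X[i] @ wi + mi[4][0] > 0) == (y[i] == 0.0)
            else:
                correct += _lib.predict(X[i : i + 1], *mi[:7], **pkw)[0] == y[i]
            keep[i] = True
        return correct / N

    def _loocv_svc(self, X) -> float:
        y = self._y
        N = self._N
        svc = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma,
                  max_iter=self.max_iter)
        correct = 0
        keep = np.ones(N, dtype=bool)
        for i in range(N):
            keep[i] = False
            yi = y[keep]
            if np.all(yi == yi[0]):
                correct += yi[0] == y[i]
            else:
                svc.fit(X[keep], yi)
                correct += svc.predict(X[i : i + 1])[0] == y[i]
            keep[i] = True
        return correct / N
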