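"""WGAN-GP generator/critic for compositional microbiome tables.

The generator maps Gaussian noise through fully connected ReLU layers to a
simplex-valued head — sparsemax (Euclidean projection onto the simplex,
able to place exact zeros) by default, softmax as an option — so every
generated row is a species-level composition (nonnegative, summing to 1).
The critic scores samples after the phylogeny
transformation (expansion to all tree nodes + log amplification) and is
trained with the Wasserstein loss plus a gradient penalty that holds its
input gradient norm near 1 (the Lipschitz surrogate).  Optimization is
RMSprop, alternating several critic steps per generator step.

Everything is plain numpy.  Backpropagation is written out by hand; for the
gradient penalty the derivative of the critic's *input gradient* with
respect to the critic weights is computed exactly, using the fact that
ReLU-family activations are piecewise linear: their second derivative
vanishes almost everywhere, so the input gradient is a product of weight
matrices interleaved with fixed activation masks, and differentiating that
product in the weights is ordinary matrix calculus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datamodel import AbundanceTable, TaxonomyTree
from .transform import amplify, amplify_grad, expansion_matrix


@dataclass
class GanConfig:
    """Training hyperparameters.

    Defaults follow the WGAN-GP recipe for this problem: gradient-penalty
    weight 10 (Wasserstein:GP loss ratio 1:10), RMSprop at 5e-5, batch 32,
    5 critic steps per generator step.
    """

    noise_dim: int = 100
    generator_layers: tuple[int, ...] = (256, 512)
    critic_layers: tuple[int, ...] = (512, 256)
    gp_weight: float = 10.0
    learning_rate: float = 5e-5
    batch_size: int = 32
    critic_steps_per_generator_step: int = 5
    max_iterations: int = 100_000
    truncation_threshold: float = 1e-4
    seed: int = 0
    output_head: str = "sparsemax"  # "sparsemax" (exact zeros) or "softmax"
    softmax_gain: float = 1.0
    leaky_slope: float = 0.2
    rmsprop_rho: float = 0.9
    rmsprop_eps: float = 1e-7
    convergence_window: int = 1000
    sample_with_replacement: bool = False
    select_best: bool = True

    def __post_init__(self) -> None:
        if self.gp_weight <= 0:
            raise ValueError("gp_weight must be positive")
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2")
        if self.critic_steps_per_generator_step < 1:
            raise ValueError("need at least one critic step per iteration")


# ---------------------------------------------------------------------------
# parameter containers and primitive nets


def _init_mlp(rng: np.random.Generator, widths: list[int]) -> list[dict[str, np.ndarray]]:
    """He-style initialization for a stack of dense layers."""
    params = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        params.append({
            "W": rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in),
            "b": np.zeros(fan_out),
        })
    return params


def _flatten(params_list: list[list[dict[str, np.ndarray]]]) -> np.ndarray:
    return np.concatenate([p[k].ravel() for params in params_list
                           for p in params for k in ("W", "b")])


class _RMSprop:
    def __init__(self, params: list[dict[str, np.ndarray]], lr: float,
                 rho: float, eps: float):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.cache = [{k: np.zeros_like(p[k]) for k in p} for p in params]

    def step(self, params, grads) -> None:
        for p, g, c in zip(params, grads, self.cache):
            for k in p:
                c[k] = self.rho * c[k] + (1.0 - self.rho) * g[k] ** 2
                p[k] -= self.lr * g[k] / (np.sqrt(c[k]) + self.eps)


def sparsemax(z: np.ndarray) -> np.ndarray:
    """Row-wise Euclidean projection onto the probability simplex.

    Unlike softmax this head reaches the boundary of the simplex, so a
    generated composition can contain *exact* zeros — the defining feature
    of sparse microbiome samples.
    """
    z = np.asarray(z, dtype=float)
    srt = np.sort(z, axis=1)[:, ::-1]
    cs = np.cumsum(srt, axis=1)
    k = np.arange(1, z.shape[1] + 1)
    support = srt * k > cs - 1.0
    k_z = support.sum(axis=1)
    tau = (cs[np.arange(z.shape[0]), k_z - 1] - 1.0) / k_z
    return np.maximum(z - tau[:, None], 0.0)


def _head_forward(logits: np.ndarray, head: str) -> np.ndarray:
    if head == "softmax":
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)
    if head == "sparsemax":
        return sparsemax(logits)
    raise ValueError(f"unknown output head {head!r}")


def _head_backward(dprobs: np.ndarray, probs: np.ndarray, head: str) -> np.ndarray:
    if head == "softmax":
        return probs * (dprobs - (dprobs * probs).sum(axis=1, keepdims=True))
    # sparsemax Jacobian: identity minus mean, restricted to the support
    supp = (probs > 0).astype(float)
    k = supp.sum(axis=1, keepdims=True)
    mean_supp = (dprobs * supp).sum(axis=1, keepdims=True) / k
    return supp * (dprobs - mean_supp)


def _gen_forward(params, z: np.ndarray, gain: float = 1.0,
                 head: str = "sparsemax") -> tuple[np.ndarray, list]:
    """ReLU hidden layers, simplex-valued output head.

    ``gain`` scales the logits (an inverse temperature); a gain > 1 lets
    the head reach very peaked compositions without huge final-layer
    weights.  Returns (probs, cache).
    """
    h = z
    cache = []
    for layer in params[:-1]:
        a = h @ layer["W"] + layer["b"]
        mask = (a > 0).astype(float)
        cache.append((h, mask))
        h = a * mask
    logits = gain * (h @ params[-1]["W"] + params[-1]["b"])
    probs = _head_forward(logits, head)
    cache.append((h, probs))
    return probs, cache


def _gen_backward(params, cache, dprobs: np.ndarray, gain: float = 1.0,
                  head: str = "sparsemax") -> list[dict[str, np.ndarray]]:
    h_last, probs = cache[-1]
    dlogits = gain * _head_backward(dprobs, probs, head)
    grads = [None] * len(params)
    grads[-1] = {"W": h_last.T @ dlogits, "b": dlogits.sum(axis=0)}
    dh = dlogits @ params[-1]["W"].T
    for l in range(len(params) - 2, -1, -1):
        h_in, mask = cache[l]
        da = dh * mask
        grads[l] = {"W": h_in.T @ da, "b": da.sum(axis=0)}
        dh = da @ params[l]["W"].T
    return grads


def _critic_forward(params, x: np.ndarray, slope: float) -> tuple[np.ndarray, list]:
    """Leaky-ReLU hidden layers, linear scalar output. Returns (scores, cache)."""
    h = x
    cache = []
    for layer in params[:-1]:
        a = h @ layer["W"] + layer["b"]
        mask = np.where(a > 0, 1.0, slope)
        cache.append((h, mask))
        h = a * mask
    out = h @ params[-1]["W"] + params[-1]["b"]
    cache.append((h, None))
    return out[:, 0], cache


def _critic_backward(params, cache, dscore: np.ndarray):
    """Backprop d(loss)/d(score) to parameter grads and the input grad."""
    h_last, _ = cache[-1]
    d = dscore[:, None]
    grads = [None] * len(params)
    grads[-1] = {"W": h_last.T @ d, "b": d.sum(axis=0)}
    dh = d @ params[-1]["W"].T
    for l in range(len(params) - 2, -1, -1):
        h_in, mask = cache[l]
        da = dh * mask
        grads[l] = {"W": h_in.T @ da, "b": da.sum(axis=0)}
        dh = da @ params[l]["W"].T
    return grads, dh


def _critic_input_grad(params, x: np.ndarray, slope: float):
    """Per-sample gradient of the critic score w.r.t. its input.

    Returns (grad, masks): grad has the shape of x; masks are the fixed
    activation derivatives needed for the second-order GP backprop.
    """
    h = x
    masks = []
    for layer in params[:-1]:
        a = h @ layer["W"] + layer["b"]
        mask = np.where(a > 0, 1.0, slope)
        masks.append(mask)
        h = a * mask
    dh = np.repeat(params[-1]["W"].T, x.shape[0], axis=0)
    for l in range(len(params) - 2, -1, -1):
        dh = (dh * masks[l]) @ params[l]["W"].T
    return dh, masks


# ---------------------------------------------------------------------------
# public model


@dataclass
class GanModel:
    """Generator parameters, critic parameters, and the training trace."""

    config: GanConfig
    theta: list  # generator layers
    omega: list  # critic layers
    taxon_ids: list[str]
    node_ids: list[str]
    expansion: np.ndarray  # leaf -> node linear map used in training
    history: dict = field(default_factory=dict)
    converged_at: int | None = None
    best_theta: list | None = None

    @property
    def n_species(self) -> int:
        return len(self.taxon_ids)

    def save(self, path: str | Path) -> None:
        arrays = {}
        for name, params in (("theta", self.theta), ("omega", self.omega)):
            for i, layer in enumerate(params):
                arrays[f"{name}_{i}_W"] = layer["W"]
                arrays[f"{name}_{i}_b"] = layer["b"]
        if self.best_theta is not None:
            for i, layer in enumerate(self.best_theta):
                arrays[f"best_theta_{i}_W"] = layer["W"]
                arrays[f"best_theta_{i}_b"] = layer["b"]
        arrays["expansion"] = self.expansion
        meta = {
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in asdict(self.config).items()},
            "taxon_ids": self.taxon_ids,
            "node_ids": self.node_ids,
            "converged_at": self.converged_at,
            "n_gen_layers": len(self.theta),
            "n_critic_layers": len(self.omega),
            "has_best": self.best_theta is not None,
            "history": {k: list(map(float, v)) for k, v in self.history.items()},
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "GanModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            cfg = dict(meta["config"])
            for k in ("generator_layers", "critic_layers"):
                cfg[k] = tuple(cfg[k])
            config = GanConfig(**cfg)
            theta = [{"W": data[f"theta_{i}_W"], "b": data[f"theta_{i}_b"]}
                     for i in range(meta["n_gen_layers"])]
            omega = [{"W": data[f"omega_{i}_W"], "b": data[f"omega_{i}_b"]}
                     for i in range(meta["n_critic_layers"])]
            best = None
            if meta["has_best"]:
                best = [{"W": data[f"best_theta_{i}_W"], "b": data[f"best_theta_{i}_b"]}
                        for i in range(meta["n_gen_layers"])]
            return cls(
                config=config, theta=theta, omega=omega,
                taxon_ids=meta["taxon_ids"], node_ids=meta["node_ids"],
                expansion=data["expansion"],
                history={k: np.array(v) for k, v in meta["history"].items()},
                converged_at=meta["converged_at"], best_theta=best,
            )


def init_model(
    config: GanConfig,
    taxon_ids: list[str],
    tree: TaxonomyTree,
    weights: dict[str, float] | None = None,
) -> GanModel:
    rng = np.random.default_rng(config.seed)
    node_ids, E = expansion_matrix(tree, taxon_ids, weights)
    gen_widths = [config.noise_dim, *config.generator_layers, len(taxon_ids)]
    critic_widths = [len(node_ids), *config.critic_layers, 1]
    return GanModel(
        config=config,
        theta=_init_mlp(rng, gen_widths),
        omega=_init_mlp(rng, critic_widths),
        taxon_ids=list(taxon_ids),
        node_ids=node_ids,
        expansion=E,
    )


def generate(model: GanModel, z: np.ndarray, truncate: bool = True,
             sample_prefix: str = "sim") -> AbundanceTable:
    """Map a noise batch to a species-level composition table.

    Rows sum to 1 before truncation; after truncation entries below the
    threshold are zeroed and rows are *not* renormalized.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[1] != model.config.noise_dim:
        raise ValueError(
            f"noise must be (batch, {model.config.noise_dim}), got {z.shape}"
        )
    theta = model.best_theta if (model.config.select_best and
                                 model.best_theta is not None) else model.theta
    probs, _ = _gen_forward(theta, z, model.config.softmax_gain, model.config.output_head)
    if truncate:
        probs = probs.copy()
        probs[probs < model.config.truncation_threshold] = 0.0
    return AbundanceTable(
        sample_ids=[f"{sample_prefix}{i}" for i in range(z.shape[0])],
        taxon_ids=list(model.taxon_ids),
        values=probs,
        normalized=not truncate,
    )


def simulate(model: GanModel, n_samples: int, seed: int) -> AbundanceTable:
    """Draw fresh seeded noise and generate ``n_samples`` compositions."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, model.config.noise_dim))
    return generate(model, z)


def critic_score(model: GanModel, batch) -> np.ndarray:
    """Unconstrained scalar score per sample of a transformed batch."""
    x = batch.values if hasattr(batch, "values") else np.asarray(batch, float)
    if x.shape[1] != len(model.node_ids):
        raise ValueError(
            f"batch width {x.shape[1]} != training node count {len(model.node_ids)}"
        )
    scores, _ = _critic_forward(model.omega, x, model.config.leaky_slope)
    return scores


def gradient_penalty(
    model: GanModel,
    real_batch,
    fake_batch,
    rng: np.random.Generator | None = None,
    return_grads: bool = False,
):
    """WGAN-GP penalty mean((||grad_xhat f(xhat)||_2 - 1)^2).

    Interpolates xhat = eps*real + (1-eps)*fake with per-sample
    eps ~ Uniform(0,1), in the critic's (transformed) input space.  With
    ``return_grads`` the exact parameter gradient of the penalty is also
    returned (biases receive zero gradient: almost everywhere they only
    enter through the activation masks, which are locally constant).
    """
    real = real_batch.values if hasattr(real_batch, "values") else np.asarray(real_batch, float)
    fake = fake_batch.values if hasattr(fake_batch, "values") else np.asarray(fake_batch, float)
    if real.shape != fake.shape:
        raise ValueError(f"batch shapes differ: {real.shape} vs {fake.shape}")
    rng = rng or np.random.default_rng(model.config.seed)
    eps = rng.uniform(size=(real.shape[0], 1))
    xhat = eps * real + (1.0 - eps) * fake

    slope = model.config.leaky_slope
    params = model.omega
    g, masks = _critic_input_grad(params, xhat, slope)
    if not np.all(np.isfinite(g)):
        raise RuntimeError("non-finite critic gradient in penalty")
    norms = np.sqrt((g ** 2).sum(axis=1))
    penalty = float(np.mean((norms - 1.0) ** 2))
    if not return_grads:
        return penalty

    batch = real.shape[0]
    safe = np.where(norms > 1e-12, norms, 1.0)
    # dP/dg per sample, mean already folded in
    c = (2.0 / batch) * ((norms - 1.0) / safe)[:, None] * g
    # prefix vectors t_l = A_l^T c and suffix vectors s_l = B_l
    t = [c]
    for l in range(len(params) - 1):
        t.append((t[-1] @ params[l]["W"]) * masks[l])
    s = [np.ones((batch, 1))]
    for l in range(len(params) - 2, -1, -1):
        s.insert(0, masks[l] * (s[0] @ params[l + 1]["W"].T))
    grads = [{"W": t[l].T @ s[l], "b": np.zeros_like(params[l]["b"])}
             for l in range(len(params))]
    return penalty, grads


def train(
    real: AbundanceTable,
    tree: TaxonomyTree,
    config: GanConfig,
    weights: dict[str, float] | None = None,
    iterations: int | None = None,
) -> GanModel:
    """Alternating WGAN-GP training.

    Each iteration runs ``critic_steps_per_generator_step`` critic updates
    (loss = mean f(fake) - mean f(real) + gp_weight * GP, minimized) followed
    by one generator update (loss = -mean f(fake)).  Both real and generated
    batches pass through the phylogeny transformation before the critic.
    All randomness (weight init, batch sampling, noise, interpolation eps)
    flows from ``config.seed``.
    """
    n_iter = config.max_iterations if iterations is None else iterations
    n = real.n_samples
    bs = config.batch_size
    if n < bs and not config.sample_with_replacement:
        raise ValueError(
            f"batch size {bs} exceeds {n} samples; set sample_with_replacement"
        )

    model = init_model(config, real.taxon_ids, tree, weights)
    rng = np.random.default_rng(config.seed)
    rng.standard_normal(1)  # decouple from init stream
    E = model.expansion
    slope = config.leaky_slope
    real_T = amplify(real.values @ E, check_domain=False)

    opt_c = _RMSprop(model.omega, config.learning_rate, config.rmsprop_rho,
                     config.rmsprop_eps)
    opt_g = _RMSprop(model.theta, config.learning_rate, config.rmsprop_rho,
                     config.rmsprop_eps)

    hist_cw: list[float] = []      # per critic step
    hist_gp: list[float] = []      # per critic step
    hist_gen: list[float] = []     # per iteration
    hist_iter_cw: list[float] = [] # per iteration (mean over its critic steps)
    hist_wmse: list[float] = []    # per iteration

    window = config.convergence_window
    prev_flat = _flatten([model.theta, model.omega])
    best_abs = np.inf
    prev_win_mean: float | None = None
    win_acc: list[float] = []

    for it in range(n_iter):
        cw_steps = []
        for _ in range(config.critic_steps_per_generator_step):
            idx = (rng.integers(0, n, bs) if config.sample_with_replacement
                   else rng.choice(n, bs, replace=False))
            rb = real_T[idx]
            z = rng.standard_normal((bs, config.noise_dim))
            fake, _ = _gen_forward(model.theta, z, config.softmax_gain, config.output_head)
            fb = amplify(fake @ E, check_domain=False)

            f_fake, cache_f = _critic_forward(model.omega, fb, slope)
            f_real, cache_r = _critic_forward(model.omega, rb, slope)
            w_loss = float(f_fake.mean() - f_real.mean())
            g_fake, _ = _critic_backward(model.omega, cache_f,
                                         np.full(bs, 1.0 / bs))
            g_real, _ = _critic_backward(model.omega, cache_r,
                                         np.full(bs, -1.0 / bs))
            gp, g_gp = gradient_penalty(model, rb, fb, rng=rng, return_grads=True)
            if not np.isfinite(w_loss) or not np.isfinite(gp):
                raise RuntimeError(f"non-finite critic loss at iteration {it}")
            grads = [{k: g_fake[l][k] + g_real[l][k] + config.gp_weight * g_gp[l][k]
                      for k in g_fake[l]} for l in range(len(model.omega))]
            opt_c.step(model.omega, grads)
            cw_steps.append(w_loss)
            hist_cw.append(w_loss)
            hist_gp.append(gp)

        z = rng.standard_normal((bs, config.noise_dim))
        fake, gen_cache = _gen_forward(model.theta, z, config.softmax_gain, config.output_head)
        v = fake @ E
        y = amplify(v, check_domain=False)
        scores, crit_cache = _critic_forward(model.omega, y, slope)
        gen_loss = float(-scores.mean())
        if not np.isfinite(gen_loss):
            raise RuntimeError(f"non-finite generator loss at iteration {it}")
        _, dy = _critic_backward(model.omega, crit_cache, np.full(bs, -1.0 / bs))
        dx = (dy * amplify_grad(v)) @ E.T
        g_grads = _gen_backward(model.theta, gen_cache, dx, config.softmax_gain,
                                config.output_head)
        opt_g.step(model.theta, g_grads)

        hist_gen.append(gen_loss)
        hist_iter_cw.append(float(np.mean(cw_steps)))
        flat = _flatten([model.theta, model.omega])
        hist_wmse.append(float(np.mean((flat - prev_flat) ** 2)))
        prev_flat = flat

        # rolling convergence check on the weight-MSE statistic
        win_acc.append(hist_wmse[-1])
        if len(win_acc) == window:
            mean_now = float(np.mean(win_acc))
            win_acc.clear()
            if (prev_win_mean is not None and model.converged_at is None
                    and abs(mean_now - prev_win_mean) < 1e-8):
                model.converged_at = it + 1
            prev_win_mean = mean_now
        if model.converged_at is not None:
            combined = abs(gen_loss + hist_iter_cw[-1])
            if combined < best_abs:
                best_abs = combined
                model.best_theta = [{k: p[k].copy() for k in p}
                                    for p in model.theta]

    model.history = {
        "critic_wasserstein": np.array(hist_cw),
        "gradient_penalty": np.array(hist_gp),
        "generator_loss": np.array(hist_gen),
        "iter_critic_wasserstein": np.array(hist_iter_cw),
        "weight_mse": np.array(hist_wmse),
    }
    return model


@dataclass
class ConvergenceStats:
    combined_wasserstein: np.ndarray
    weight_mse: np.ndarray
    converged: bool | None   # None = not yet assessable
    converged_at: int | None


def convergence_stats(history: dict, window: int = 1000) -> ConvergenceStats:
    """Convergence diagnostics from a training history.

    Statistic 1 is the per-iteration sum of generator and critic
    Wasserstein losses; statistic 2 is the mean squared per-parameter
    change between consecutive iterations.  Training is declared converged
    when the difference of the statistic-2 means over two consecutive
    windows falls below 1e-8.
    """
    gen = np.asarray(history["generator_loss"], dtype=float)
    cw = np.asarray(history["iter_critic_wasserstein"], dtype=float)
    wmse = np.asarray(history["weight_mse"], dtype=float)
    if gen.size == 0:
        raise ValueError("empty history")
    combined = gen + cw
    n_windows = wmse.size // window
    if n_windows < 2:
        return ConvergenceStats(combined, wmse, None, None)
    means = wmse[: n_windows * window].reshape(n_windows, window).mean(axis=1)
    diffs = np.abs(np.diff(means))
    hits = np.nonzero(diffs < 1e-8)[0]
    if hits.size:
        return ConvergenceStats(combined, wmse, True, int((hits[0] + 2) * window))
    return ConvergenceStats(combined, wmse, False, None)
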