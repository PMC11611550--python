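"""Adversarial training: objectives, schedule, splits, loop and ablations.

The generator objective is the pix2pix composite
``L_G = lambda1 * L_adv + lambda2 * L1(SD, G(LD))`` with ``lambda1 = 1`` and
``lambda2 = 100`` by default; the discriminator minimises the usual
real/fake cross-entropy on patch logits.  Ablation axes: BCE vs MSE (LSGAN)
adversarial form, an optional differentiable FID penalty, discriminator
on/off (off reduces training to supervised L1 regression), attention
type/position, and presence of the large input convolution.

Optimisation is Adam with betas (0.5, 0.999), batch size 1, a constant
learning rate of 1e-4 for the first ``lr_constant_epochs`` epochs and a
linear decay to zero at the final epoch.  The checkpoint kept is the one
with the highest validation SSIM.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grad import Tensor
from .metrics import SliceFeatureExtractor, ssim
from .networks import Discriminator, DiscriminatorSpec, Generator, GeneratorSpec
from .nn import Adam, bce_with_logits
from .ssab import SSABConfig


@dataclass
class LossWeights:
    lambda1: float = 1.0    # adversarial term
    lambda2: float = 100.0  # L1 reconstruction term
    fid_weight: float = 0.0

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.fid_weight) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class TrainConfig:
    adversarial_form: str = "BCE"   # "BCE" or "MSE"
    saturating: bool = False        # printed log(1-D) generator form
    epochs: int = 400
    lr: float = 1e-4
    lr_constant_epochs: int = 100
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 1
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    discriminator_enabled: bool = True
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)

    def __post_init__(self):
        if not math.isclose(sum(self.split), 1.0, abs_tol=1e-9):
            raise ValueError("split fractions must sum to 1")
        if self.epochs < self.lr_constant_epochs:
            raise ValueError("epochs must be >= lr_constant_epochs")


def smoke_config(seed: int = 0, epochs: int = 30, attention_type: str = "ssab",
                 **overrides) -> TrainConfig:
    """Desk-scale configuration: 2-level generator, base 8, sized for 32^3."""
    gen = GeneratorSpec(levels=2, base_channels=8, ssab_positions=frozenset({2}),
                        attention_type=attention_type,
                        ssab=SSABConfig(sa_reduction=8, ca_reduction=8), seed=seed)
    dis = DiscriminatorSpec(layers=2, base_channels=8, seed=seed)
    cfg = TrainConfig(epochs=epochs, lr_constant_epochs=max(1, epochs // 3),
                      seed=seed, generator=gen, discriminator=dis, **overrides)
    return cfg


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _check_finite(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise FloatingPointError(f"non-finite {name} component: {value}")


def generator_loss(d_scores_fake: Tensor | None, dn: Tensor, sd: Tensor,
                   weights: LossWeights, form: str = "BCE",
                   saturating: bool = False,
                   fid_term: Tensor | None = None) -> tuple[Tensor, dict]:
    """lambda1 * adversarial + lambda2 * L1 (+ fid_weight * FID)."""
    if dn.shape != sd.shape:
        raise ValueError("denoised/reference shape mismatch")
    l1 = (sd - dn).abs().mean()
    if d_scores_fake is None:
        adv = Tensor(np.float64(0.0))
    elif form.upper() == "BCE":
        if saturating:
            adv = -bce_with_logits(d_scores_fake, 0)  # E[log(1 - D(fake))]
        else:
            adv = bce_with_logits(d_scores_fake, 1)   # non-saturating -E[log D(fake)]
    elif form.upper() == "MSE":
        adv = ((d_scores_fake - 1.0) ** 2).mean()
    else:
        raise ValueError(f"unknown adversarial form {form!r}")
    total = weights.lambda1 * adv + weights.lambda2 * l1
    comps = {"adv": adv.item(), "l1": l1.item(), "fid": 0.0}
    if fid_term is not None:
        total = total + weights.fid_weight * fid_term
        comps["fid"] = fid_term.item()
    for k, v in comps.items():
        _check_finite(k, v)
    _check_finite("total", total.item())
    return total, comps


def discriminator_loss(d_scores_real: Tensor, d_scores_fake: Tensor,
                       form: str = "BCE") -> Tensor:
    """-E[log D(real)] - E[log(1 - D(fake))] on logits (or the MSE form)."""
    if form.upper() == "BCE":
        loss = bce_with_logits(d_scores_real, 1) + bce_with_logits(d_scores_fake, 0)
    elif form.upper() == "MSE":
        loss = ((d_scores_real - 1.0) ** 2).mean() + (d_scores_fake**2).mean()
    else:
        raise ValueError(f"unknown adversarial form {form!r}")
    _check_finite("discriminator loss", loss.item())
    return loss


def _trace_sqrt_product(sa: Tensor, sb: np.ndarray) -> Tensor:
    """Tr((Sa Sb)^(1/2)) with gradient w.r.t. Sa (Sb is the fixed reference)."""
    eb, ub = np.linalg.eigh(sb)
    sb_half = (ub * np.sqrt(np.clip(eb, 0.0, None))) @ ub.T
    m = sb_half @ sa.data @ sb_half
    em, um = np.linalg.eigh(m)
    em_c = np.clip(em, 0.0, None)
    val = np.sqrt(em_c).sum()
    # d Tr(M^(1/2)) / d Sa = 1/2 Sb^(1/2) M^(-1/2) Sb^(1/2)
    inv_sqrt = (um * (1.0 / np.sqrt(np.clip(em_c, 1e-12, None)))) @ um.T
    grad_sa = 0.5 * sb_half @ inv_sqrt @ sb_half

    def back(out):
        if sa.requires_grad:
            sa._accum(out.grad * grad_sa)

    return Tensor._make(np.float64(val), (sa,), back)


def fid_loss_term(dn_batch: list[Tensor], sd_batch: list[np.ndarray],
                  extractor: SliceFeatureExtractor) -> Tensor:
    """Differentiable Fréchet distance between Gaussian feature fits of the
    denoised and reference batches; gradients flow to the denoised volumes
    only (the extractor and the reference statistics are fixed)."""
    feats = [extractor.features_tensor(t) for t in dn_batch]
    fa = feats[0] if len(feats) == 1 else _stack_rows(feats)
    n = fa.shape[0]
    if n < 2:
        raise ValueError("need at least 2 feature vectors for a covariance")
    fb = extractor.features([np.asarray(v) for v in sd_batch])
    mu_a = fa.mean(axis=0)
    xa = fa - mu_a.reshape(1, -1)
    sa = (xa.transpose(1, 0) @ xa) * (1.0 / (n - 1))
    mu_b = fb.mean(axis=0)
    sb = np.atleast_2d(np.cov(fb, rowvar=False))
    diff = mu_a - Tensor(mu_b)
    tr_ab = _trace_sqrt_product(sa, sb)
    d2 = (diff * diff).sum() + _trace(sa) + float(np.trace(sb)) - 2.0 * tr_ab
    return d2


def _stack_rows(tensors: list[Tensor]) -> Tensor:
    from .grad import concat
    return concat(tensors, axis=0)


def _trace(sq: Tensor) -> Tensor:
    n = sq.shape[0]
    return sq[np.arange(n), np.arange(n)].sum()


# ---------------------------------------------------------------------------
# Schedule and splits
# ---------------------------------------------------------------------------

def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Constant lr for the first ``lr_constant_epochs``, then linear to zero."""
    if epoch < 0 or epoch > cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    if epoch < cfg.lr_constant_epochs:
        return cfg.lr
    return cfg.lr * (cfg.epochs - epoch) / (cfg.epochs - cfg.lr_constant_epochs)


def split_dataset(n: int, fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive subject-level train/val/test index sets."""
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    n_train = int(math.floor(fractions[0] * n))
    n_val = int(math.floor(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"empty split at n={n} with fractions {fractions}")
    perm = np.random.default_rng(seed).permutation(n)
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    generator: Generator
    history: pd.DataFrame
    best_epoch: int
    best_val_ssim: float
    splits: tuple[np.ndarray, np.ndarray, np.ndarray]
    diverged: bool = False


def train(pairs: list[tuple[np.ndarray, np.ndarray]], cfg: TrainConfig,
          extractor: SliceFeatureExtractor | None = None,
          progress: bool = False) -> TrainResult:
    """Train on preprocessed (low, standard) array pairs in [-1, 1].

    Alternates discriminator and generator updates per volume (batch size 1);
    when the discriminator is disabled the loop is supervised L1 regression.
    The best-validation-SSIM generator state is restored at the end.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to train")
    tr_idx, va_idx, te_idx = split_dataset(len(pairs), cfg.split, cfg.seed)
    rng = np.random.default_rng(cfg.seed)

    gen = Generator(cfg.generator)
    g_opt = Adam(gen.parameters(), lr=cfg.lr, betas=cfg.betas)
    use_d = cfg.discriminator_enabled and cfg.discriminator.enabled
    if use_d:
        disc = Discriminator(cfg.discriminator)
        d_opt = Adam(disc.parameters(), lr=cfg.lr, betas=cfg.betas)
    w = cfg.weights
    if w.fid_weight > 0 and extractor is None:
        extractor = SliceFeatureExtractor()

    rows = []
    best_state, best_val, best_epoch = gen.state_dict(), -np.inf, -1
    diverged = False
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        g_opt.lr = lr
        if use_d:
            d_opt.lr = lr
        order = rng.permutation(tr_idx)
        ep = {"loss_d": [], "loss_g": [], "adv": [], "l1": [], "fid": [], "total": []}
        try:
            for i in order:
                ld = Tensor(np.asarray(pairs[i][0], dtype=np.float32)[None, None])
                sd_arr = np.asarray(pairs[i][1], dtype=np.float32)
                sd = Tensor(sd_arr[None, None])
                dn = gen(ld)

                if use_d:
                    d_real = disc(ld, sd)
                    d_fake = disc(ld, dn.detach())
                    d_loss = discriminator_loss(d_real, d_fake, cfg.adversarial_form)
                    d_opt.zero_grad()
                    d_loss.backward()
                    d_opt.step()
                    ep["loss_d"].append(d_loss.item())
                    d_fake_for_g = disc(ld, dn)
                else:
                    d_fake_for_g = None
                    ep["loss_d"].append(0.0)

                fid_t = None
                if w.fid_weight > 0:
                    fid_t = fid_loss_term([dn], [sd_arr[None, None]], extractor)
                g_loss, comps = generator_loss(d_fake_for_g, dn, sd, w,
                                               cfg.adversarial_form, cfg.saturating,
                                               fid_t)
                g_opt.zero_grad()
                g_loss.backward()
                g_opt.step()
                ep["loss_g"].append(g_loss.item())
                ep["total"].append(g_loss.item())
                for k in ("adv", "l1", "fid"):
                    ep[k].append(comps[k])
        except FloatingPointError:
            diverged = True

        val_ssim = float(np.mean([
            ssim(gen.denoise(pairs[i][0]), pairs[i][1], data_range=2.0)
            for i in va_idx]))
        rows.append({
            "epoch": epoch, "lr": lr,
            "loss_d": float(np.mean(ep["loss_d"])) if ep["loss_d"] else np.nan,
            "loss_g": float(np.mean(ep["loss_g"])) if ep["loss_g"] else np.nan,
            "adv": float(np.mean(ep["adv"])) if ep["adv"] else np.nan,
            "l1": float(np.mean(ep["l1"])) if ep["l1"] else np.nan,
            "fid": float(np.mean(ep["fid"])) if ep["fid"] else np.nan,
            "val_ssim": val_ssim,
        })
        if progress:
            print(f"epoch {epoch:3d} lr {lr:.2e} G {rows[-1]['loss_g']:.4f} "
                  f"val_ssim {val_ssim:.4f}")
        if not diverged and val_ssim > best_val:
            best_val, best_epoch, best_state = val_ssim, epoch, gen.state_dict()
        if diverged:
            break

    gen.load_state_dict(best_state)
    return TrainResult(gen, pd.DataFrame(rows), best_epoch, best_val,
                       (tr_idx, va_idx, te_idx), diverged)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(result: TrainResult, cfg: TrainConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "generator_spec": cfg.generator,
        "state": result.generator.state_dict(),
        "seed": cfg.seed,
        "best_epoch": result.best_epoch,
        "best_val_ssim": result.best_val_ssim,
        "config": asdict(cfg),
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)
    return path


def load_checkpoint(path: str | Path) -> Generator:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    gen = Generator(payload["generator_spec"])
    gen.load_state_dict(payload["state"])
    return gen
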