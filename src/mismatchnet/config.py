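"""Run configuration shared by the fitting, weighting and evaluation layers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

MODELS = ("enet", "lasso", "ridge", "wenet", "wlasso", "wridge")


@dataclass
class RunConfig:
    """Knobs for a full fit/evaluate run.

    alpha : elastic-net mixing used by the (w)enet models (lasso/ridge are
        pinned at 1/0); cv_folds : folds for lambda selection; lambda_rule :
        "min" or "1se"; zero_coef_policy : what an undiscriminating marker's
        infinite weight becomes ("exclude" drops it, "cap" caps it at
        ``cap * max finite weight``); binary_family : loss of the
        train-vs-test discriminator; normalize : NRMSE denominator
        ("mean" | "sd" | "range"); n_lambda / lambda_min_ratio / tol /
        max_sweeps : solver path settings (ratio None = 1e-2 if n < p else
        1e-4).
    """

    alpha: float = 0.5
    cv_folds: int = 10
    lambda_rule: str = "min"
    zero_coef_policy: str = "exclude"
    cap: float = 10.0
    binary_family: str = "gaussian"
    normalize: str = "mean"
    seed: int = 0
    models: tuple = MODELS
    traits: tuple | None = None
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    tol: float = 1e-7
    max_sweeps: int = 100_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")
        if self.zero_coef_policy not in ("exclude", "cap"):
            raise ValueError("zero_coef_policy must be 'exclude' or 'cap'")
        if self.cap <= 1:
            raise ValueError("cap must exceed 1")
        if self.binary_family not in ("gaussian", "logistic"):
            raise ValueError("binary_family must be 'gaussian' or 'logistic'")
        if self.normalize not in ("mean", "sd", "range"):
            raise ValueError("normalize must be 'mean', 'sd' or 'range'")
        self.models = tuple(self.models)
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model '{m}'")
        if self.traits is not None:
            self.traits = tuple(self.traits)

    def config_hash(self) -> str:
        """Stable digest of the configuration (logged for reproducibility)."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def derive_seed(base_seed: int, *parts) -> int:
    """Deterministic per-task seed below 2**31.

    Keyed by arbitrary labels so adding a model/fold does not perturb the
    random streams of the others.
    """
    key = "|".join([str(base_seed)] + [str(p) for p in parts])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
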