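"""NAdam optimizer (Adam with Nesterov momentum)."""

from __future__ import annotations

import numpy as np

from mapgan.nn.layers import Parameter


class NAdam:
    """NAdam with the standard momentum-decay schedule (psi = 0.004).

    Update per step t (1-based)::

        mu_t   = beta1 * (1 - 0.5 * 0.96 ** (t * psi))
        mu_t+1 = beta1 * (1 - 0.5 * 0.96 ** ((t + 1) * psi))
        m <- beta1 m + (1 - beta1) g ;  v <- beta2 v + (1 - beta2) g²
        m_hat = mu_t+1 m / (1 - Π mu_1..t+1) + (1 - mu_t) g / (1 - Π mu_1..t)
        v_hat = v / (1 - beta2^t)
        p <- p - lr * m_hat / (sqrt(v_hat) + eps)
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        momentum_decay: float = 4e-3,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.psi = momentum_decay
        self.t = 0
        self.mu_product = 1.0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        t = self.t
        b1, b2 = self.beta1, self.beta2
        mu_t = b1 * (1.0 - 0.5 * 0.96 ** (t * self.psi))
        mu_next = b1 * (1.0 - 0.5 * 0.96 ** ((t + 1) * self.psi))
        self.mu_product *= mu_t
        mu_prod_next = self.mu_product * mu_next
        bias2 = 1.0 - b2**t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            m_hat = mu_next * m / (1.0 - mu_prod_next) + (1.0 - mu_t) * g / (
                1.0 - self.mu_product
            )
            v_hat = v / bias2
            p.data -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(
                p.data.dtype
            )

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "mu_product": self.mu_product,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.mu_product = float(state["mu_product"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
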