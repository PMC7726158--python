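"""Reversible nucleotide substitution models (GTR/REV and HKY85).

Rate matrices are built over the fixed base order (A, C, G, T), satisfy
detailed balance with respect to the stationary frequencies, and are
normalized so one unit of branch length equals one expected substitution
per site. Transition probabilities P(t) = exp(Qt) are computed by
eigendecomposition of the symmetrized matrix diag(sqrt(pi)) Q
diag(1/sqrt(pi)), which has a real spectrum for any reversible Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: order of the six GTR exchangeability parameters
EXCH_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))  # AC AG AT CG CT GT


class ModelParameterError(ValueError):
    """Invalid substitution-model parameter (non-positive rate or frequency)."""


def _validate_pi(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,):
        raise ModelParameterError(f"pi must have 4 entries, got shape {pi.shape}")
    if np.any(pi <= 0):
        raise ModelParameterError("stationary frequencies must be positive")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ModelParameterError(f"stationary frequencies must sum to 1, got {pi.sum()}")
    return pi / pi.sum()


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible nucleotide model: kind ('REV' or 'HKY'), pi, parameters, Q.

    ``Q`` is normalized to one expected substitution per unit time.
    The eigendecomposition used by :func:`transition_matrix` is cached.
    """

    kind: str
    pi: np.ndarray
    exchangeabilities: np.ndarray | None = None
    kappa: float | None = None
    Q: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _eig: tuple = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def transition_matrix(self, t: float) -> np.ndarray:
        return transition_matrix(self, t)

    def to_text(self) -> str:
        lines = [f"kind: {self.kind}", "pi: " + " ".join(f"{x:.12g}" for x in self.pi)]
        if self.kind == "REV":
            lines.append(
                "exchangeabilities: " + " ".join(f"{x:.12g}" for x in self.exchangeabilities)
            )
        else:
            lines.append(f"kappa: {self.kappa:.12g}")
        return "\n".join(lines) + "\n"

    @staticmethod
    def from_text(text: str) -> "SubstitutionModel":
        fields = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or ":" not in line:
                continue
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
        kind = fields["kind"]
        pi = np.array([float(x) for x in fields["pi"].split()])
        if kind == "REV":
            exch = [float(x) for x in fields["exchangeabilities"].split()]
            return build_model("REV", pi, exchangeabilities=exch)
        return build_model("HKY", pi, kappa=float(fields["kappa"]))


def _finalize(kind: str, pi: np.ndarray, R: np.ndarray, **extra) -> SubstitutionModel:
    """Build normalized Q from symmetric exchangeability matrix R and pi."""
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.dot(pi, np.diag(Q))
    Q = Q / rate
    # symmetrized eigendecomposition for exp(Qt)
    sqrt_pi = np.sqrt(pi)
    S = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    left = vecs.T * sqrt_pi[None, :]          # rows: V^T D^{1/2}
    right = (vecs.T / sqrt_pi[None, :]).T     # D^{-1/2} V
    model = SubstitutionModel(kind=kind, pi=pi, Q=Q, **extra)
    object.__setattr__(model, "_eig", (vals, right, left))
    return model


def build_model(kind: str, pi, *, exchangeabilities=None, kappa: float | None = None,
                ) -> SubstitutionModel:
    """Construct a REV (GTR) or HKY85 model.

    Parameters
    ----------
    kind : 'REV' or 'HKY'
    pi : stationary frequencies over (A, C, G, T)
    exchangeabilities : six positive symmetric rates in the order
        AC, AG, AT, CG, CT, GT (REV only)
    kappa : transition/transversion rate ratio (HKY only)
    """
    pi = _validate_pi(pi)
    R = np.zeros((4, 4))
    if kind == "REV":
        if exchangeabilities is None:
            raise ModelParameterError("REV requires 6 exchangeabilities")
        exch = np.asarray(exchangeabilities, dtype=float)
        if exch.shape != (6,) or np.any(exch <= 0):
            raise ModelParameterError("REV needs 6 positive exchangeabilities")
        for (i, j), r in zip(EXCH_PAIRS, exch):
            R[i, j] = R[j, i] = r
        return _finalize("REV", pi, R, exchangeabilities=exch)
    if kind == "HKY":
        if kappa is None or kappa <= 0:
            raise ModelParameterError("HKY requires kappa > 0")
        R[:] = 1.0
        # transitions: A<->G (purines), C<->T (pyrimidines)
        R[0, 2] = R[2, 0] = kappa
        R[1, 3] = R[3, 1] = kappa
        np.fill_diagonal(R, 0.0)
        return _finalize("HKY", pi, R, kappa=float(kappa))
    raise ModelParameterError(f"unknown model kind {kind!r}")


def jukes_cantor() -> SubstitutionModel:
    """JC69 as the kappa=1, uniform-frequency special case of HKY."""
    return build_model("HKY", np.full(4, 0.25), kappa=1.0)


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, P(0) = I."""
    if not np.isfinite(t) or t < 0:
        raise ModelParameterError(f"branch length must be finite and >= 0, got {t}")
    vals, right, left = model._eig
    P = (right * np.exp(vals * t)[None, :]) @ left
    np.maximum(P, 0.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def transition_matrices(model: SubstitutionModel, ts: np.ndarray) -> np.ndarray:
    """Stack of P(t) for an array of branch lengths, shape (len(ts), 4, 4)."""
    ts = np.asarray(ts, dtype=float)
    if np.any(~np.isfinite(ts)) or np.any(ts < 0):
        raise ModelParameterError("branch lengths must be finite and >= 0")
    vals, right, left = model._eig
    P = np.einsum("ij,nj,jk->nik", right, np.exp(np.outer(ts, vals)), left)
    np.maximum(P, 0.0, out=P)
    P /= P.sum(axis=2, keepdims=True)
    return P


def hky_closed_form(pi, kappa: float, t: float) -> np.ndarray:
    """Analytic HKY85 transition probabilities (independent of the eigen path).

    Standard closed form: for target base j with frequency pi_j, let
    Pi_j = pi of j's purine/pyrimidine class, A_j = 1 + Pi_j (kappa - 1).
    With the matrix normalized to one expected substitution per unit time
    (rate beta), P_ij(t) follows the textbook three-term expression.
    """
    pi = _validate_pi(np.asarray(pi, float))
    piY = pi[1] + pi[3]
    piR = pi[0] + pi[2]
    beta = 1.0 / (2.0 * piR * piY + 2.0 * kappa * (pi[0] * pi[2] + pi[1] * pi[3]))
    P = np.zeros((4, 4))
    purine = (True, False, True, False)
    for i in range(4):
        for j in range(4):
            PiJ = piR if purine[j] else piY
            Aj = 1.0 + PiJ * (kappa - 1.0)
            e_bt = np.exp(-beta * t)
            e_At = np.exp(-beta * t * Aj)
            if i == j:
                P[i, j] = (pi[j] + pi[j] * (1.0 / PiJ - 1.0) * e_bt
                           + (PiJ - pi[j]) / PiJ * e_At)
            elif purine[i] == purine[j]:  # transition
                P[i, j] = (pi[j] + pi[j] * (1.0 / PiJ - 1.0) * e_bt
                           - pi[j] / PiJ * e_At)
            else:  # transversion
                P[i, j] = pi[j] * (1.0 - e_bt)
    return P
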