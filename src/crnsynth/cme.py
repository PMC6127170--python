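"""Continuous-time Markov chain analysis of CRNs via the chemical master
equation.

A CRN with strictly positive rates and a finite set of initial states induces
a CTMC over its reachable state space.  The off-diagonal generator entry
``q_ij`` is the summed propensity of the reactions taking state ``x_i`` to
state ``x_j``; the diagonal carries the negative row sum.  Terminal states
(no reaction enabled) have all-zero rows, i.e. they are absorbing.  The
transient probability vector obeys the chemical master equation
``dpi/dt = pi Q``, solved here by dense matrix exponentials for moderate
state counts and by a stiff (BDF) integrator on the sparse generator
otherwise.

The correctness score of a CRN against a specification (the averaged
probability that each computation halts in its required final state by the
deadline ``t_F``) is evaluated per path predicate and aggregated by the
unweighted arithmetic mean.  Because terminal states are absorbing, the
score per predicate equals the probability mass absorbed, by time ``t_F``,
into terminal states satisfying the final predicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .model import (
    CRN,
    CRNError,
    State,
    StateSpace,
    propensity,
    reachable_states,
    DEFAULT_STATE_CAP,
)
from .specs import Specification, eval_predicate

__all__ = [
    "CTMC",
    "ScoreReport",
    "ScoreEvaluator",
    "NonAbsorbingError",
    "build_ctmc",
    "transient_distribution",
    "spec_score",
    "absorption_probabilities",
    "expected_termination_time",
]

#: Dense matrix exponentials are used up to this state count.
_DENSE_LIMIT = 600

#: Relative/absolute tolerances for the ODE fallback.
_RTOL, _ATOL = 1e-8, 1e-12


class NonAbsorbingError(CRNError):
    """A recurrent class with no terminal state was detected where
    almost-sure termination is required."""


@dataclass
class CTMC:
    """Explicit-state CTMC: reachable states, sparse generator, initial
    distribution and terminality mask."""

    space: StateSpace
    Q: sp.csr_matrix
    pi0: np.ndarray

    @property
    def states(self) -> list[State]:
        return self.space.states

    @property
    def terminal(self) -> np.ndarray:
        return self.space.terminal

    def __len__(self) -> int:
        return len(self.space.states)


def build_ctmc(crn: CRN, rates=None, initial=None,
               cap: int = DEFAULT_STATE_CAP, volume: float = 1.0) -> CTMC:
    """Build the CTMC of ``crn`` from a set of initial states.

    ``rates`` overrides the CRN's rate constants (one strictly positive value
    per reaction).  ``volume`` divides every bimolecular propensity, the
    classical density scaling for a reaction vessel of relative size
    ``volume``.  The initial distribution is uniform over ``initial``.
    """
    if initial is None:
        raise CRNError("an initial state set is required")
    if rates is not None:
        crn = crn.with_rates(rates)
    if volume != 1.0:
        if volume <= 0:
            raise CRNError("volume must be positive")
        crn = crn.with_rates(crn.rates / float(volume))
    space = reachable_states(crn, initial, cap=cap)
    n = len(space.states)
    rows, cols, vals = [], [], []
    for i, x in enumerate(space.states):
        out = {}
        for r in crn.reactions:
            a = propensity(r, x)
            if a > 0:
                y = tuple(v - rr + pp for v, rr, pp in
                          zip(x, r.reactants, r.products))
                j = space.index[y]
                out[j] = out.get(j, 0.0) + a
        total = 0.0
        for j, a in out.items():
            rows.append(i)
            cols.append(j)
            vals.append(a)
            total += a
        if total > 0:
            rows.append(i)
            cols.append(i)
            vals.append(-total)
    Q = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    pi0 = np.zeros(n)
    for i in space.initial_indices:
        pi0[i] += 1.0
    pi0 /= pi0.sum()
    return CTMC(space=space, Q=Q, pi0=pi0)


def transient_distribution(ctmc: CTMC, t: float, method: str = "auto") -> np.ndarray:
    """Solve the chemical master equation: the distribution ``pi_t``.

    ``method`` is ``'expm'`` (dense matrix exponential), ``'ode'`` (stiff BDF
    integration at rtol 1e-8 / atol 1e-12) or ``'auto'``.
    """
    if t < 0:
        raise CRNError("time must be non-negative")
    if t == 0:
        return ctmc.pi0.copy()
    n = len(ctmc)
    if method == "auto":
        method = "expm" if n <= _DENSE_LIMIT else "ode"
    if method == "expm":
        P = scipy.linalg.expm(ctmc.Q.toarray() * t)
        pi = ctmc.pi0 @ P
    elif method == "ode":
        QT = ctmc.Q.T.tocsr()
        sol = solve_ivp(lambda _, y: QT @ y, (0.0, t), ctmc.pi0,
                        method="BDF", jac=QT, rtol=_RTOL, atol=_ATOL)
        if not sol.success:
            raise CRNError(f"CME integration failed: {sol.message}")
        pi = sol.y[:, -1]
    else:
        raise CRNError(f"unknown method {method!r}")
    pi = np.clip(pi, 0.0, None)
    s = pi.sum()
    if not (abs(s - 1.0) < 1e-6):
        raise CRNError(f"probability mass not conserved (sum={s})")
    return pi / s


def _transient_block(ctmc: CTMC):
    """Indices of transient (non-terminal) states and the corresponding
    generator blocks Q_TT, Q_TA."""
    term = ctmc.terminal
    t_idx = np.flatnonzero(~term)
    a_idx = np.flatnonzero(term)
    Q = ctmc.Q.tocsr()
    return t_idx, a_idx, Q[t_idx][:, t_idx], Q[t_idx][:, a_idx]


def _check_absorbing(ctmc: CTMC) -> None:
    """Verify every non-terminal state can reach a terminal state."""
    n = len(ctmc)
    term = ctmc.terminal
    if term.all():
        return
    if not term.any():
        raise NonAbsorbingError("no terminal state is reachable")
    # reverse reachability from terminal states on the transition graph
    A = (ctmc.Q > 0).astype(np.int8)
    reached = np.zeros(n, dtype=bool)
    for t0 in np.flatnonzero(term):
        order = csgraph.breadth_first_order(A.T, i_start=int(t0),
                                            return_predecessors=False)
        reached[order] = True
    if not reached.all():
        raise NonAbsorbingError(
            "some states cannot reach any terminal state "
            "(non-absorbing recurrent class)")


def absorption_probabilities(ctmc: CTMC) -> dict[State, float]:
    """Eventual absorption probability for each terminal state.

    Solves the first-step linear system restricted to transient states;
    requires (and checks) that every recurrent class is a terminal state.
    """
    _check_absorbing(ctmc)
    term = ctmc.terminal
    result = {s: 0.0 for s, t in zip(ctmc.states, term) if t}
    t_idx, a_idx, Qtt, Qta = _transient_block(ctmc)
    pi0_a = ctmc.pi0[a_idx]
    if len(t_idx):
        U = spla.spsolve(-Qtt.tocsc(), Qta.tocsc())
        if sp.issparse(U):
            U = np.asarray(U.todense())
        U = U.reshape(len(t_idx), len(a_idx))
        absorbed = ctmc.pi0[t_idx] @ U + pi0_a
    else:
        absorbed = pi0_a
    for j, p in zip(a_idx, np.atleast_1d(absorbed)):
        result[ctmc.states[j]] = float(p)
    return result


def expected_termination_time(crn: CRN, rates=None, x0: State = None,
                              volume: float = 1.0,
                              cap: int = DEFAULT_STATE_CAP) -> float:
    """Expected hitting time of the terminal set from ``x0``.

    Propensities are divided by ``volume`` (density scaling), so expected
    times scale linearly with the volume.  Raises
    :class:`NonAbsorbingError` when termination is not almost sure.
    """
    if x0 is None:
        raise CRNError("an initial state is required")
    ctmc = build_ctmc(crn, rates=rates, initial=[x0], cap=cap, volume=volume)
    _check_absorbing(ctmc)
    term = ctmc.terminal
    i0 = ctmc.space.index[tuple(int(v) for v in x0)]
    if term[i0]:
        return 0.0
    t_idx, _, Qtt, _ = _transient_block(ctmc)
    tau = spla.spsolve(-Qtt.tocsc(), np.ones(len(t_idx)))
    pos = {int(i): k for k, i in enumerate(t_idx)}
    return float(tau[pos[i0]])


# ---------------------------------------------------------------------------
# Specification scoring
# ---------------------------------------------------------------------------

@dataclass
class ScoreReport:
    """Per-predicate halting-correctness probabilities and their mean."""

    labels: list[str]
    per_predicate: np.ndarray
    average: float
    rates: np.ndarray
    t_F: float

    def as_dict(self) -> dict:
        return {
            "average": self.average,
            "per_predicate": {l: float(p) for l, p in
                              zip(self.labels, self.per_predicate)},
            "rates": [float(k) for k in self.rates],
            "t_F": self.t_F,
        }


class ScoreEvaluator:
    """Repeated scoring of one CRN against one specification.

    The reachable state space, per-reaction propensity matrices and
    acceptance masks are rate-independent and precomputed once; each call to
    :meth:`score` assembles the generator for a rate vector and computes the
    probability of halting correctly by ``t_F``.

    When every transient state can reach the terminal set, eventual
    absorption probabilities are obtained from the first-step linear system,
    and a fourth-moment Chebyshev bound ``P(T > t_F) <= E[T^4]/t_F^4`` on the
    hitting time certifies (when < 1e-9) that the deadline correction is
    negligible; otherwise the exact transient solution is computed by matrix
    exponential.
    """

    def __init__(self, crn: CRN, spec: Specification,
                 cap: int = DEFAULT_STATE_CAP):
        self.crn = crn
        self.spec = spec
        names = crn.species_names
        for s in spec.input_species + spec.output_species:
            if s not in names:
                raise CRNError(f"specification species {s!r} missing from CRN")
        self.t_F = spec.t_F
        self._per_psi = []
        unit = crn.with_rates(np.ones(len(crn.reactions)))
        for psi in spec.predicates:
            x0 = psi.initial_state(names)
            space = reachable_states(unit, [x0], cap=cap)
            n = len(space.states)
            i0 = space.index[x0]
            # per-reaction unit-rate propensity matrices, dense
            Qm = np.zeros((len(crn.reactions), n, n))
            for m, r in enumerate(unit.reactions):
                for i, x in enumerate(space.states):
                    a = propensity(r, x)
                    if a > 0:
                        y = tuple(v - rr + pp for v, rr, pp in
                                  zip(x, r.reactants, r.products))
                        j = space.index[y]
                        Qm[m, i, j] += a
                        Qm[m, i, i] -= a
            terminal = space.terminal
            accept = np.array(
                [t and eval_predicate(psi.phiF, s, names)
                 for s, t in zip(space.states, terminal)], dtype=bool)
            t_idx = np.flatnonzero(~terminal)
            # can every transient state reach the terminal set?
            can_absorb = False
            if terminal.any() and len(t_idx):
                A = sp.csr_matrix((np.abs(Qm).sum(axis=0) > 0).astype(np.int8))
                reached = np.zeros(n, dtype=bool)
                for t0 in np.flatnonzero(terminal):
                    order = csgraph.breadth_first_order(
                        A.T, i_start=int(t0), return_predecessors=False)
                    reached[order] = True
                can_absorb = bool(reached[t_idx].all())
            elif terminal.any():
                can_absorb = True
            self._per_psi.append({
                "label": psi.label, "x0": i0, "Qm": Qm,
                "terminal": terminal, "accept": accept,
                "t_idx": t_idx, "can_absorb": can_absorb,
            })

    def _score_one(self, d, k: np.ndarray) -> float:
        Q = np.tensordot(k, d["Qm"], axes=1)
        i0 = d["x0"]
        accept = d["accept"]
        if d["terminal"][i0]:
            return float(accept[i0])
        t_idx = d["t_idx"]
        if d["can_absorb"]:
            Qtt = Q[np.ix_(t_idx, t_idx)]
            try:
                lu = scipy.linalg.lu_factor(-Qtt)
                ones = np.ones(len(t_idx))
                m = ones
                for j in range(1, 5):
                    m = j * scipy.linalg.lu_solve(lu, m)
                pos = {int(i): kk for kk, i in enumerate(t_idx)}
                tail = m[pos[i0]] / self.t_F ** 4
                if tail < 1e-9:
                    b = Q[np.ix_(t_idx, np.flatnonzero(accept))].sum(axis=1)
                    u = scipy.linalg.lu_solve(lu, b)
                    return float(min(1.0, max(0.0, u[pos[i0]])))
            except scipy.linalg.LinAlgError:
                pass
        pi = np.zeros(Q.shape[0])
        pi[i0] = 1.0
        pi = pi @ scipy.linalg.expm(Q * self.t_F)
        return float(min(1.0, max(0.0, pi[accept].sum())))

    def per_predicate(self, rates) -> np.ndarray:
        k = np.asarray(rates, dtype=float)
        if k.shape != (len(self.crn.reactions),) or (k <= 0).any():
            raise CRNError("need one strictly positive rate per reaction")
        return np.array([self._score_one(d, k) for d in self._per_psi])

    def score(self, rates) -> float:
        return float(self.per_predicate(rates).mean())

    def report(self, rates) -> ScoreReport:
        per = self.per_predicate(rates)
        return ScoreReport(
            labels=[d["label"] for d in self._per_psi],
            per_predicate=per, average=float(per.mean()),
            rates=np.asarray(rates, dtype=float), t_F=self.t_F)


def spec_score(crn: CRN, rates=None, spec: Specification = None,
               cap: int = DEFAULT_STATE_CAP) -> ScoreReport:
    """Average probability that the CRN halts correctly by the deadline.

    For each path predicate, the CTMC is built from the phi0-pinned initial
    state, the master equation is solved to ``t_F``, and the mass on terminal
    states satisfying phiF is reported; the score is the unweighted mean over
    predicates.
    """
    if spec is None:
        raise CRNError("a specification is required")
    if rates is None:
        rates = crn.rates
    return ScoreEvaluator(crn, spec, cap=cap).report(rates)
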