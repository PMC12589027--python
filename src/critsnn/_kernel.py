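"""Vectorised multi-step simulation kernel.

One source function implements the per-step semantics defined in
:mod:`critsnn.model`; it is compiled with numba when available and also
kept as a plain-Python twin so the two paths can be checked against each
other (and against the fine-grained reference operations).

Synaptic delays are realised with circular per-step accumulation buffers
(``ring_exc``/``ring_inh`` of shape (RING, n)): slot ``step % RING``
holds the conductance increments due for delivery at that step.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    njit = None
    HAVE_NUMBA = False

RING = 32  # must exceed the longest delay in steps + 1

# float-constant vector layout
(F_AM, F_VREST, F_VTH, F_EEXC, F_EINH, F_GREST, F_DAMPA, F_DGABA, F_DREC,
 F_PREF, F_INVB, F_U, F_GME, F_GMI, F_AE, F_AEBE, F_C1, F_C2,
 F_DECE, F_DECI1, F_DECI2) = range(21)
# int-constant vector layout
(I_DEE, I_DOTH, I_REFE, I_REFI) = range(4)


def pack_constants(np_, sp_):
    """Pack neuron and STDP parameters into flat constant vectors."""
    dt = np_.dt
    f = np.empty(21, dtype=np.float64)
    f[F_AM] = dt / np_.tau_m
    f[F_VREST] = np_.v_rest
    f[F_VTH] = np_.v_th
    f[F_EEXC] = np_.E_exc
    f[F_EINH] = np_.E_inh
    f[F_GREST] = np_.g_rest
    f[F_DAMPA] = math.exp(-dt / np_.tau_AMPA)
    f[F_DGABA] = math.exp(-dt / np_.tau_GABA)
    f[F_DREC] = math.exp(-dt / np_.tau_rec)
    f[F_PREF] = np_.escape_prefactor
    f[F_INVB] = 1.0 / np_.b
    f[F_U] = np_.U
    f[F_GME] = np_.g_max_exc
    f[F_GMI] = np_.g_max_inh
    f[F_AE] = sp_.A_E
    f[F_AEBE] = sp_.A_E * sp_.beta_E
    f[F_C1] = sp_.c1
    f[F_C2] = sp_.c2
    f[F_DECE] = math.exp(-dt / sp_.tau_E)
    f[F_DECI1] = math.exp(-dt / sp_.tau_I1)
    f[F_DECI2] = math.exp(-dt / sp_.tau_I2)
    i = np.empty(4, dtype=np.int64)
    i[I_DEE] = np_.delay_steps_EE
    i[I_DOTH] = np_.delay_steps_other
    i[I_REFE] = np_.ref_steps_exc
    i[I_REFI] = np_.ref_steps_inh
    if max(i[I_DEE], i[I_DOTH]) + 1 >= RING:
        raise ValueError("synaptic delay exceeds the ring-buffer capacity")
    return f, i


def _make_step_chunk():
    def step_chunk(u, step0, v, g_exc, g_inh, x, w, ref_until, is_exc,
                   trE, trI1, trI2, ring_exc, ring_inh,
                   fc, ic, plast_on, record_currents, rec_E, rec_I,
                   spike_steps, spike_units):
        S, n = u.shape
        n_spk = 0
        buf = np.empty(n, dtype=np.int64)
        for s in range(S):
            gs = step0 + s
            pos = gs % RING
            # 1. deliver due synaptic events
            for j in range(n):
                g_exc[j] += ring_exc[pos, j]
                ring_exc[pos, j] = 0.0
                g_inh[j] += ring_inh[pos, j]
                ring_inh[pos, j] = 0.0
            # 2. subthreshold update
            for j in range(n):
                dv = fc[F_AM] * (
                    (fc[F_VREST] - v[j]) * fc[F_GREST]
                    + (fc[F_EEXC] - v[j]) * g_exc[j]
                    + (fc[F_EINH] - v[j]) * g_inh[j]
                )
                vj = v[j] + dv
                if gs < ref_until[j]:
                    vj = fc[F_VREST]
                v[j] = vj
                if record_currents:
                    rec_E[s, j] = (fc[F_EEXC] - vj) * g_exc[j]
                    rec_I[s, j] = (fc[F_EINH] - vj) * g_inh[j]
                g_exc[j] *= fc[F_DAMPA]
                g_inh[j] *= fc[F_DGABA]
                x[j] = 1.0 - (1.0 - x[j]) * fc[F_DREC]
                trE[j] *= fc[F_DECE]
                trI1[j] *= fc[F_DECI1]
                trI2[j] *= fc[F_DECI2]
            gs1 = gs + 1
            # 3. escape-noise spike draws
            k = 0
            for j in range(n):
                p = fc[F_PREF] * math.exp((v[j] - fc[F_VTH]) * fc[F_INVB])
                if p > 1.0:
                    p = 1.0
                if u[s, j] < p and gs1 >= ref_until[j]:
                    buf[k] = j
                    k += 1
            if k == 0:
                continue
            # 4a. all-to-all STDP; pairs run over strictly earlier
            # spikes, so traces are incremented only after every
            # spiker's row (pre-role) and column (post-role) updates.
            if plast_on:
                for q in range(k):
                    i = buf[q]
                    if is_exc[i]:
                        for j in range(n):
                            if j != i:
                                wv = w[i, j] - fc[F_AEBE] * trE[j]
                                w[i, j] = min(max(wv, 0.0), 1.0)
                    else:
                        for j in range(n):
                            if j != i:
                                wv = w[i, j] + fc[F_C1] * trI1[j] \
                                    - fc[F_C2] * trI2[j]
                                w[i, j] = min(max(wv, 0.0), 1.0)
                    for j in range(n):
                        if j != i:
                            if is_exc[j]:
                                wv = w[j, i] + fc[F_AE] * trE[j]
                            else:
                                wv = w[j, i] + fc[F_C1] * trI1[j] \
                                    - fc[F_C2] * trI2[j]
                            w[j, i] = min(max(wv, 0.0), 1.0)
                for q in range(k):
                    i = buf[q]
                    trE[i] += 1.0
                    trI1[i] += 1.0
                    trI2[i] += 1.0
            # 4b. resets, refractoriness, STP release and delayed queueing
            for q in range(k):
                i = buf[q]
                v[i] = fc[F_VREST]
                if is_exc[i]:
                    ref_until[i] = gs1 + ic[I_REFE]
                else:
                    ref_until[i] = gs1 + ic[I_REFI]
                r = fc[F_U] * x[i]
                if is_exc[i]:
                    pe = (gs1 + ic[I_DEE]) % RING
                    po = (gs1 + ic[I_DOTH]) % RING
                    for j in range(n):
                        if j != i:
                            inc = r * w[i, j] * fc[F_GME]
                            if is_exc[j]:
                                ring_exc[pe, j] += inc
                            else:
                                ring_exc[po, j] += inc
                else:
                    po = (gs1 + ic[I_DOTH]) % RING
                    for j in range(n):
                        if j != i:
                            ring_inh[po, j] += r * w[i, j] * fc[F_GMI]
                x[i] = x[i] - fc[F_U] * x[i]
                spike_steps[n_spk] = gs1
                spike_units[n_spk] = i
                n_spk += 1
        return n_spk

    return step_chunk


step_chunk_py = _make_step_chunk()
if HAVE_NUMBA:
    step_chunk_jit = njit(cache=True)(_make_step_chunk())
else:  # pragma: no cover
    step_chunk_jit = step_chunk_py
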