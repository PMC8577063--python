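"""Low-level integration engine.

All cells of the network are packed into flat per-compartment arrays and
advanced by a single jitted loop.  The membrane step is implicit in voltage:
channel gating is updated first by exponential Euler, then the cable
equation (tree-structured axial coupling) is solved exactly per cell and
time step with a Hines elimination.  Synaptic conductances are folded into
the implicit voltage step; gap junctions use the partner voltage from the
previous step (semi-implicit).

Units: ms, mV, nA, uS, nF.  Sign convention: synaptic and channel currents
are I = g * (V - E); a positive injected current (``itonic``/external)
depolarizes.

Compartment packing contract: compartments of one cell are contiguous, the
root (soma-side) compartment comes first and every parent index is smaller
than the child index, so a single backward/forward sweep solves the tree.
"""

import numpy as np
from numba import njit

__all__ = ["run_network", "step_compartments", "rate_constants"]


@njit(cache=True, fastmath=True)
def _exprel(u, k):
    """u / (1 - exp(-u/k)) with its limit k at u -> 0."""
    x = u / k
    if abs(x) < 1e-6:
        return k * (1.0 + x / 2.0)
    return u / (1.0 - np.exp(-x))


@njit(cache=True, fastmath=True)
def rate_constants(v):
    """Forward/backward rates (1/ms) of the Na (m, h) and K-DR (n) gates."""
    am = 0.32 * _exprel(v + 54.0, 4.0)
    bm = 0.28 * _exprel(-(v + 27.0), 5.0)
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    an = 0.032 * _exprel(v + 52.0, 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return am, bm, ah, bh, an, bn


# Slow-gate time constants (ms): K-M adaptation and H-current
TAU_Z = 100.0
TAU_R = 180.0


@njit(cache=True, fastmath=True)
def step_compartments(v, m, h, n, z, r,
                      parent, gax, cm, gna, gkdr, gkm, gh, gleak, eleak, phi,
                      ena, ek, eh,
                      gs_extra, bs_extra, dt, diag, rhs):
    """Advance gating and voltages of all compartments by one step in place.

    gs_extra/bs_extra carry additional conductance and current-source terms
    (synapses, gap junctions, injected currents): the local current balance
    solved implicitly is  C dV/dt = -(G_ion+gs)V + (B_ion+bs) + axial.
    """
    nc = v.size
    kz = 1.0 - np.exp(-dt / TAU_Z)
    kr = 1.0 - np.exp(-dt / TAU_R)
    for c in range(nc):
        V = v[c]
        G = gleak[c] + gs_extra[c]
        B = gleak[c] * eleak[c] + bs_extra[c]
        if gna[c] > 0.0:
            am, bm, ah, bh, an, bn = rate_constants(V)
            p = phi[c]
            s = am + bm
            minf = am / s
            m[c] = minf + (m[c] - minf) * np.exp(-dt * s)
            s = ah + bh
            hinf = ah / s
            h[c] = hinf + (h[c] - hinf) * np.exp(-dt * s * p)
            gna_t = gna[c] * m[c] * m[c] * m[c] * h[c]
            G += gna_t
            B += gna_t * ena
            if gkdr[c] > 0.0:
                s = an + bn
                ninf = an / s
                n[c] = ninf + (n[c] - ninf) * np.exp(-dt * s * p)
                n2 = n[c] * n[c]
                gk_t = gkdr[c] * n2 * n2
                G += gk_t
                B += gk_t * ek
        if gkm[c] > 0.0:
            zinf = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
            z[c] += (zinf - z[c]) * kz
            gm_t = gkm[c] * z[c]
            G += gm_t
            B += gm_t * ek
        if gh[c] > 0.0:
            rinf = 1.0 / (1.0 + np.exp((V + 80.0) / 10.0))
            r[c] += (rinf - r[c]) * kr
            gh_t = gh[c] * r[c]
            G += gh_t
            B += gh_t * eh
        diag[c] = cm[c] / dt + G
        rhs[c] = cm[c] / dt * V + B
        if parent[c] >= 0:
            diag[c] += gax[c]
            diag[parent[c]] += gax[c]
    # Hines elimination (children have larger indices than their parent)
    for c in range(nc - 1, 0, -1):
        p = parent[c]
        if p >= 0:
            f = gax[c] / diag[c]
            diag[p] -= gax[c] * f
            rhs[p] += rhs[c] * f
    for c in range(nc):
        p = parent[c]
        if p < 0:
            v[c] = rhs[c] / diag[c]
        else:
            v[c] = (rhs[c] + gax[c] * v[p]) / diag[c]


# run_network status codes
OK = 0
ERR_SPIKE_OVERFLOW = 1
ERR_RING_OVERFLOW = 2
ERR_BLOWUP = 3


@njit(cache=True)
def run_network(n_steps, dt,
                parent, gax, cm, gna, gkdr, gkm, gh, gleak, eleak, phi,
                ena, ek, eh,
                v, m, h, n, z, r,
                soma_idx, thresh, refrac_steps, last_spike_step,
                taur, taud, syn_e, syn_norm,
                Ar, Ad,
                ring_count, ring_comp, ring_k, ring_w,
                proj_ptr, proj_comp, proj_k, proj_w, proj_delay,
                ext_step, ext_unit,
                itonic,
                gj_a, gj_b, gj_g,
                rec_every, imem_chan, imem_out, vm_idx, vm_out,
                spk_cell, spk_time):
    """Main simulation loop.  Returns (n_spikes, status, bad_comp, bad_step).

    Projections are CSR-indexed by presynaptic unit: units 0..ncell-1 are
    network cells, ncell.. are external generators.  ``ext_step``/``ext_unit``
    list the pre-sampled generator spikes sorted by integration step.
    Delivered conductance events wait in a ring buffer of per-step event
    lists (delays are >= 1 step and < ring depth).
    """
    nc = v.size
    ncell = soma_idx.size
    K = taur.size
    D = ring_count.size
    ring_cap = ring_comp.shape[1]
    dr = np.exp(-dt / taur)
    dd = np.exp(-dt / taud)
    gs = np.zeros(nc)
    bs = np.zeros(nc)
    diag = np.empty(nc)
    rhs = np.empty(nc)
    vprev_soma = np.empty(ncell)
    nchan = imem_out.shape[1]
    imem_acc = np.zeros(max(nchan, 1))
    ep = 0
    nspk = 0
    rec_row = 0
    for s in range(n_steps):
        slot = s % D
        cnt = ring_count[slot]
        for i in range(cnt):
            c = ring_comp[slot, i]
            k = ring_k[slot, i]
            inc = ring_w[slot, i] * syn_norm[k]
            Ar[c, k] += inc
            Ad[c, k] += inc
        ring_count[slot] = 0
        while ep < ext_step.size and ext_step[ep] == s:
            u = ext_unit[ep]
            for e in range(proj_ptr[u], proj_ptr[u + 1]):
                dslot = (s + proj_delay[e]) % D
                idx = ring_count[dslot]
                if idx >= ring_cap:
                    return nspk, ERR_RING_OVERFLOW, 0, s
                ring_comp[dslot, idx] = proj_comp[e]
                ring_k[dslot, idx] = proj_k[e]
                ring_w[dslot, idx] = proj_w[e]
                ring_count[dslot] = idx + 1
            ep += 1
        for c in range(nc):
            G = 0.0
            B = itonic[c]
            for k in range(K):
                g = Ad[c, k] - Ar[c, k]
                if g > 0.0:
                    G += g
                    B += g * syn_e[k]
            gs[c] = G
            bs[c] = B
        for j in range(gj_a.size):
            a = gj_a[j]
            b = gj_b[j]
            g = gj_g[j]
            gs[a] += g
            bs[a] += g * v[b]
            gs[b] += g
            bs[b] += g * v[a]
        for i in range(ncell):
            vprev_soma[i] = v[soma_idx[i]]
        step_compartments(v, m, h, n, z, r,
                          parent, gax, cm, gna, gkdr, gkm, gh, gleak, eleak,
                          phi, ena, ek, eh, gs, bs, dt, diag, rhs)
        for c in range(nc):
            for k in range(K):
                Ar[c, k] *= dr[k]
                Ad[c, k] *= dd[k]
        t_now = (s + 1) * dt
        for i in range(ncell):
            sc = soma_idx[i]
            if (v[sc] >= thresh[i] and vprev_soma[i] < thresh[i]
                    and (s - last_spike_step[i]) >= refrac_steps):
                last_spike_step[i] = s
                if nspk >= spk_cell.size:
                    return nspk, ERR_SPIKE_OVERFLOW, 0, s
                spk_cell[nspk] = i
                spk_time[nspk] = t_now
                nspk += 1
                for e in range(proj_ptr[i], proj_ptr[i + 1]):
                    dslot = (s + proj_delay[e]) % D
                    idx = ring_count[dslot]
                    if idx >= ring_cap:
                        return nspk, ERR_RING_OVERFLOW, 0, s
                    ring_comp[dslot, idx] = proj_comp[e]
                    ring_k[dslot, idx] = proj_k[e]
                    ring_w[dslot, idx] = proj_w[e]
                    ring_count[dslot] = idx + 1
        if nchan > 0:
            # transmembrane current of a compartment equals the net axial
            # current into it (Kirchhoff), so per-cell sums vanish exactly
            for c in range(nc):
                p = parent[c]
                if p >= 0:
                    J = gax[c] * (v[p] - v[c])
                    ch = imem_chan[c]
                    if ch >= 0:
                        imem_acc[ch] += J
                    chp = imem_chan[p]
                    if chp >= 0:
                        imem_acc[chp] -= J
        if (s + 1) % rec_every == 0 and rec_row < imem_out.shape[0]:
            for ch in range(nchan):
                imem_out[rec_row, ch] = imem_acc[ch] / rec_every
                imem_acc[ch] = 0.0
            for iv in range(vm_idx.size):
                vm_out[rec_row, iv] = v[vm_idx[iv]]
            rec_row += 1
        for c in range(nc):
            if not (-200.0 < v[c] < 200.0):
                return nspk, ERR_BLOWUP, c, s
    return nspk, OK, 0, n_steps


@njit(cache=True)
def run_single_cell(n_steps, dt,
                    parent, gax, cm, gna, gkdr, gkm, gh, gleak, eleak, phi,
                    ena, ek, eh,
                    v, m, h, n, z, r,
                    iext, thresh, refrac_steps,
                    v_trace, spk_time):
    """Integrate one isolated cell with constant injected currents.

    ``v_trace`` (n_steps,) records the root-compartment voltage; returns the
    number of detected somatic spikes (written into ``spk_time``).
    """
    nc = v.size
    gs = np.zeros(nc)
    diag = np.empty(nc)
    rhs = np.empty(nc)
    nspk = 0
    last = -10 ** 9
    for s in range(n_steps):
        vprev = v[0]
        step_compartments(v, m, h, n, z, r,
                          parent, gax, cm, gna, gkdr, gkm, gh, gleak, eleak,
                          phi, ena, ek, eh, gs, iext, dt, diag, rhs)
        if (v[0] >= thresh and vprev < thresh and (s - last) >= refrac_steps):
            last = s
            if nspk < spk_time.size:
                spk_time[nspk] = (s + 1) * dt
            nspk += 1
        v_trace[s] = v[0]
    return nspk
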