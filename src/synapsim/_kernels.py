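"""Numba kernels for the particle simulators.

Both phases share the same organization dynamics (lateral diffusion +
tau-leap Bernoulli reactions at probability 1 - exp(-k*dt) per step); the
response kernel adds point-particle glutamate diffusing in the cleft slab
and per-receptor Markov channel gating.

State encodings (kept in sync with organization.py):
  PSD-95: 0 FREE, 1 PALMITOYLATED, 2 BOUND, 3 INACTIVE
  AMPAR:  0 INTERNAL, 1 SURFACE_FREE, 2 TRAPPED

Geometry vector: [synapse_r, psd_r, nd_cx, nd_cy, nd_r]
Rate-probability vector: [p_palm_on, p_palm_off, p_bind, p_unbind,
                          p_endo, p_exo, p_inact]
Sigma vector (nm/axis/step): [amp_free, amp_trapped, psd_free, psd_palm]
"""

import numpy as np
from numba import njit

PSD_FREE, PSD_PALM, PSD_BOUND, PSD_INACT = 0, 1, 2, 3
AMP_INTERNAL, AMP_FREE, AMP_TRAPPED = 0, 1, 2


@njit(cache=True)
def _reflect_disc(x, y, cx, cy, r):
    """Radial reflection into the disc (cx, cy, r)."""
    dx = x - cx
    dy = y - cy
    d = np.sqrt(dx * dx + dy * dy)
    if d > r:
        f = (2.0 * r - d) / d
        if f < 0.0:
            f = 0.0
        x = cx + dx * f
        y = cy + dy * f
    return x, y


@njit(cache=True)
def _uniform_disc(cx, cy, r):
    rr = r * np.sqrt(np.random.random())
    th = 2.0 * np.pi * np.random.random()
    return cx + rr * np.cos(th), cy + rr * np.sin(th)


@njit(cache=True)
def _org_step(psd_pos, psd_state, psd_partner,
              amp_pos, amp_state, amp_partner,
              geom, prob, sig, reaction_radius):
    """One organization step, in place.  Order: diffusion, then
    palmitoylation, binding, unbinding, endo/exocytosis, inactivation."""
    syn_r, psd_r, nd_cx, nd_cy, nd_r = geom[0], geom[1], geom[2], geom[3], geom[4]
    p_palm_on, p_palm_off = prob[0], prob[1]
    p_bind, p_unbind = prob[2], prob[3]
    p_endo, p_exo, p_inact = prob[4], prob[5], prob[6]
    sig_af, sig_at, sig_pf, sig_pp = sig[0], sig[1], sig[2], sig[3]
    n_psd = psd_state.shape[0]
    n_amp = amp_state.shape[0]
    nd_r2 = nd_r * nd_r
    rr2 = reaction_radius * reaction_radius
    gate_r = nd_r + reaction_radius

    # --- diffusion -------------------------------------------------------
    for i in range(n_amp):
        s = amp_state[i]
        if s == AMP_FREE:
            if sig_af > 0.0:
                x = amp_pos[i, 0] + sig_af * np.random.normal()
                y = amp_pos[i, 1] + sig_af * np.random.normal()
                x, y = _reflect_disc(x, y, 0.0, 0.0, syn_r)
                amp_pos[i, 0] = x
                amp_pos[i, 1] = y
        elif s == AMP_TRAPPED:
            if sig_at > 0.0:
                x = amp_pos[i, 0] + sig_at * np.random.normal()
                y = amp_pos[i, 1] + sig_at * np.random.normal()
                x, y = _reflect_disc(x, y, nd_cx, nd_cy, nd_r)
                amp_pos[i, 0] = x
                amp_pos[i, 1] = y
            j = amp_partner[i]
            psd_pos[j, 0] = amp_pos[i, 0]   # bound pair moves together
            psd_pos[j, 1] = amp_pos[i, 1]
    for i in range(n_psd):
        s = psd_state[i]
        if s == PSD_FREE:
            if sig_pf > 0.0:
                x = psd_pos[i, 0] + sig_pf * np.random.normal()
                y = psd_pos[i, 1] + sig_pf * np.random.normal()
                x, y = _reflect_disc(x, y, 0.0, 0.0, psd_r)
                psd_pos[i, 0] = x
                psd_pos[i, 1] = y
        elif s == PSD_PALM:
            if sig_pp > 0.0:
                x = psd_pos[i, 0] + sig_pp * np.random.normal()
                y = psd_pos[i, 1] + sig_pp * np.random.normal()
                x, y = _reflect_disc(x, y, nd_cx, nd_cy, nd_r)
                psd_pos[i, 0] = x
                psd_pos[i, 1] = y

    # --- palmitoylation --------------------------------------------------
    # First-order channels fire per eligible particle with the same
    # Bernoulli probability, so the number of events per step is
    # Binomial(m, p); drawing the count once and selecting uniformly
    # among eligible particles is an exact, draw-sparse equivalent.
    if p_palm_on > 0.0:
        m = 0
        for i in range(n_psd):
            if psd_state[i] == PSD_FREE:
                dx = psd_pos[i, 0] - nd_cx
                dy = psd_pos[i, 1] - nd_cy
                if dx * dx + dy * dy <= nd_r2:
                    m += 1
        k = np.random.binomial(m, p_palm_on) if m > 0 else 0
        for _ in range(k):
            r = int(np.random.random() * m)
            c = 0
            for i in range(n_psd):
                if psd_state[i] == PSD_FREE:
                    dx = psd_pos[i, 0] - nd_cx
                    dy = psd_pos[i, 1] - nd_cy
                    if dx * dx + dy * dy <= nd_r2:
                        if c == r:
                            psd_state[i] = PSD_PALM
                            break
                        c += 1
            m -= 1
    if p_palm_off > 0.0:
        m = 0
        for i in range(n_psd):
            if psd_state[i] == PSD_PALM:
                m += 1
        k = np.random.binomial(m, p_palm_off) if m > 0 else 0
        for _ in range(k):
            r = int(np.random.random() * m)
            c = 0
            for i in range(n_psd):
                if psd_state[i] == PSD_PALM:
                    if c == r:
                        psd_state[i] = PSD_FREE
                        break
                    c += 1
            m -= 1

    # --- AMPAR trapping (mass-action per receptor-slot pair) -------------
    if p_bind > 0.0:
        for i in range(n_amp):
            if amp_state[i] != AMP_FREE:
                continue
            dxg = amp_pos[i, 0] - nd_cx
            dyg = amp_pos[i, 1] - nd_cy
            if dxg * dxg + dyg * dyg > gate_r * gate_r:
                continue           # cannot reach any palmitoylated slot
            n_pairs = 0
            best = -1
            best_d2 = 1.0e30
            for j in range(n_psd):
                if psd_state[j] != PSD_PALM:
                    continue
                dx = amp_pos[i, 0] - psd_pos[j, 0]
                dy = amp_pos[i, 1] - psd_pos[j, 1]
                d2 = dx * dx + dy * dy
                if d2 <= rr2:
                    n_pairs += 1
                    if d2 < best_d2:
                        best_d2 = d2
                        best = j
            if n_pairs > 0:
                p_any = 1.0 - (1.0 - p_bind) ** n_pairs
                if np.random.random() < p_any:
                    amp_state[i] = AMP_TRAPPED
                    amp_partner[i] = best
                    psd_state[best] = PSD_BOUND
                    psd_partner[best] = i
                    psd_pos[best, 0] = amp_pos[i, 0]
                    psd_pos[best, 1] = amp_pos[i, 1]

    # --- untrapping ------------------------------------------------------
    if p_unbind > 0.0:
        m = 0
        for i in range(n_amp):
            if amp_state[i] == AMP_TRAPPED:
                m += 1
        k = np.random.binomial(m, p_unbind) if m > 0 else 0
        for _ in range(k):
            r = int(np.random.random() * m)
            c = 0
            for i in range(n_amp):
                if amp_state[i] == AMP_TRAPPED:
                    if c == r:
                        j = amp_partner[i]
                        psd_state[j] = PSD_PALM
                        psd_partner[j] = -1
                        amp_state[i] = AMP_FREE
                        amp_partner[i] = -1
                        break
                    c += 1
            m -= 1

    # --- exo / endocytosis (exo first, from the pre-step internal pool) --
    if p_exo > 0.0:
        m = 0
        for i in range(n_amp):
            if amp_state[i] == AMP_INTERNAL:
                m += 1
        k = np.random.binomial(m, p_exo) if m > 0 else 0
        for _ in range(k):
            r = int(np.random.random() * m)
            c = 0
            for i in range(n_amp):
                if amp_state[i] == AMP_INTERNAL:
                    if c == r:
                        x, y = _uniform_disc(0.0, 0.0, syn_r)
                        amp_pos[i, 0] = x
                        amp_pos[i, 1] = y
                        amp_state[i] = AMP_FREE
                        break
                    c += 1
            m -= 1
    if p_endo > 0.0:
        m = 0
        for i in range(n_amp):
            if amp_state[i] == AMP_FREE:
                m += 1
        k = np.random.binomial(m, p_endo) if m > 0 else 0
        for _ in range(k):
            r = int(np.random.random() * m)
            c = 0
            for i in range(n_amp):
                if amp_state[i] == AMP_FREE:
                    if c == r:
                        amp_state[i] = AMP_INTERNAL
                        break
                    c += 1
            m -= 1

    # --- PSD-95 inactivation --------------------------------------------
    if p_inact > 0.0:
        m = 0
        for i in range(n_psd):
            if psd_state[i] != PSD_INACT:
                m += 1
        k = np.random.binomial(m, p_inact) if m > 0 else 0
        for _ in range(k):
            r = int(np.random.random() * m)
            c = 0
            for i in range(n_psd):
                s = psd_state[i]
                if s != PSD_INACT:
                    if c == r:
                        if s == PSD_BOUND:
                            j = psd_partner[i]
                            amp_state[j] = AMP_FREE
                            amp_partner[j] = -1
                            psd_partner[i] = -1
                        psd_state[i] = PSD_INACT
                        break
                    c += 1
            m -= 1


@njit(cache=True)
def org_run(psd_pos, psd_state, psd_partner,
            amp_pos, amp_state, amp_partner,
            geom, prob, sig, reaction_radius,
            n_steps, record_stride, counts_out,
            track_start, track_stride, track_pos, track_state,
            seed):
    """Run *n_steps* organization steps, recording count rows every
    *record_stride* steps and AMPAR positions every *track_stride* steps
    from *track_start* (strides <= 0 disable recording)."""
    np.random.seed(seed)
    syn_r, psd_r, nd_cx, nd_cy, nd_r = geom[0], geom[1], geom[2], geom[3], geom[4]
    nd_r2 = nd_r * nd_r
    n_psd = psd_state.shape[0]
    n_amp = amp_state.shape[0]
    rec_i = 0
    trk_i = 0
    for step in range(1, n_steps + 1):
        _org_step(psd_pos, psd_state, psd_partner,
                  amp_pos, amp_state, amp_partner,
                  geom, prob, sig, reaction_radius)
        if record_stride > 0 and step % record_stride == 0:
            palm_nd = 0
            active = 0
            for i in range(n_psd):
                s = psd_state[i]
                if s != PSD_INACT:
                    active += 1
                if s == PSD_PALM or s == PSD_BOUND:
                    dx = psd_pos[i, 0] - nd_cx
                    dy = psd_pos[i, 1] - nd_cy
                    if dx * dx + dy * dy <= nd_r2:
                        palm_nd += 1
            trapped = 0
            surface = 0
            for i in range(n_amp):
                if amp_state[i] == AMP_TRAPPED:
                    trapped += 1
                if amp_state[i] != AMP_INTERNAL:
                    surface += 1
            counts_out[rec_i, 0] = step
            counts_out[rec_i, 1] = palm_nd
            counts_out[rec_i, 2] = trapped
            counts_out[rec_i, 3] = surface
            counts_out[rec_i, 4] = active
            rec_i += 1
        if (track_stride > 0 and step >= track_start
                and (step - track_start) % track_stride == 0
                and trk_i < track_pos.shape[0]):
            for i in range(n_amp):
                track_pos[trk_i, i, 0] = amp_pos[i, 0]
                track_pos[trk_i, i, 1] = amp_pos[i, 1]
                track_state[trk_i, i] = amp_state[i]
            trk_i += 1
    return rec_i, trk_i


@njit(cache=True)
def _psd_diffuse(psd_pos, psd_state, geom, sig_pf, sig_pp):
    """Diffusion of unbound PSD-95 only (bound ones follow their AMPAR)."""
    psd_r = geom[1]
    nd_cx, nd_cy, nd_r = geom[2], geom[3], geom[4]
    for i in range(psd_state.shape[0]):
        s = psd_state[i]
        if s == PSD_FREE and sig_pf > 0.0:
            x = psd_pos[i, 0] + sig_pf * np.random.normal()
            y = psd_pos[i, 1] + sig_pf * np.random.normal()
            x, y = _reflect_disc(x, y, 0.0, 0.0, psd_r)
            psd_pos[i, 0] = x
            psd_pos[i, 1] = y
        elif s == PSD_PALM and sig_pp > 0.0:
            x = psd_pos[i, 0] + sig_pp * np.random.normal()
            y = psd_pos[i, 1] + sig_pp * np.random.normal()
            x, y = _reflect_disc(x, y, nd_cx, nd_cy, nd_r)
            psd_pos[i, 0] = x
            psd_pos[i, 1] = y


@njit(cache=True)
def response_run(psd_pos, psd_state, psd_partner,
                 amp_pos, amp_state, amp_partner,
                 channel_state,
                 geom, prob, sig, reaction_radius,
                 uni_n, uni_to, uni_p, uni_rel,
                 bind_p, bind_target, open_state,
                 glut_pos, glut_active, n_activated,
                 pulse_steps, per_release,
                 release_x, release_y, release_z,
                 sig_glut, cleft_h, esc_r2, bind_r2,
                 n_steps, step_offset, open_out, seed, psd_stride):
    """Run *n_steps* µs-resolution response steps, in place.

    Glutamate blocks of *per_release* molecules are activated at the
    absolute step indices in *pulse_steps* (compared against
    ``step_offset + local step``).  ``open_out[local step]`` receives the
    open-channel count after each step.  Returns the updated number of
    activated glutamate slots.
    """
    np.random.seed(seed)
    n_amp = amp_state.shape[0]
    cap = glut_active.shape[0]
    n_act = n_activated
    # PSD-95 moves ~0.3 nm per µs step; its diffusion is advanced every
    # psd_stride steps with variance scaled accordingly (exact for the
    # Brownian increment, reflection applied at the coarse step).
    sig_pf = sig[2] * np.sqrt(psd_stride)
    sig_pp = sig[3] * np.sqrt(psd_stride)
    sig_fine = sig.copy()
    sig_fine[2] = 0.0
    sig_fine[3] = 0.0

    for local in range(n_steps):
        step = step_offset + local
        if psd_stride > 0 and step % psd_stride == 0:
            _psd_diffuse(psd_pos, psd_state, geom, sig_pf, sig_pp)
        # --- glutamate release ------------------------------------------
        for p in range(pulse_steps.shape[0]):
            if pulse_steps[p] == step:
                for g in range(n_act, min(n_act + per_release, cap)):
                    glut_pos[g, 0] = release_x
                    glut_pos[g, 1] = release_y
                    glut_pos[g, 2] = release_z
                    glut_active[g] = 1
                n_act = min(n_act + per_release, cap)

        # --- organization dynamics (µs probabilities) -------------------
        _org_step(psd_pos, psd_state, psd_partner,
                  amp_pos, amp_state, amp_partner,
                  geom, prob, sig_fine, reaction_radius)

        # --- first-order channel transitions ----------------------------
        for i in range(n_amp):
            if amp_state[i] == AMP_INTERNAL:
                if channel_state[i] != 0:
                    channel_state[i] = 0   # internalized receptors reset
                continue
            s = channel_state[i]
            m = uni_n[s]
            if m == 0:
                continue
            u = np.random.random()
            acc = 0.0
            for t in range(m):
                acc += uni_p[s, t]
                if u < acc:
                    if uni_rel[s, t] == 1:
                        # return one glutamate at the receptor position
                        for g in range(n_act):
                            if glut_active[g] == 0:
                                glut_active[g] = 1
                                glut_pos[g, 0] = amp_pos[i, 0]
                                glut_pos[g, 1] = amp_pos[i, 1]
                                glut_pos[g, 2] = 0.0
                                break
                    channel_state[i] = uni_to[s, t]
                    break

        # --- glutamate diffusion, escape, binding -----------------------
        any_glut = False
        for g in range(n_act):
            if glut_active[g] == 1:
                any_glut = True
                break
        if any_glut:
            # spatial hash of binding-capable receptors (cell edge =
            # binding radius, so a 3x3 neighbourhood covers the capture
            # disc); rebuilt each step, receptors are few
            esc_r = np.sqrt(esc_r2)
            bind_r = np.sqrt(bind_r2)
            ncell = int(2.0 * esc_r / bind_r) + 3
            head = np.full(ncell * ncell, -1, dtype=np.int64)
            nxt = np.full(n_amp, -1, dtype=np.int64)
            for i in range(n_amp):
                if amp_state[i] != AMP_INTERNAL and bind_p[channel_state[i]] > 0.0:
                    cx = int((amp_pos[i, 0] + esc_r) / bind_r) + 1
                    cy = int((amp_pos[i, 1] + esc_r) / bind_r) + 1
                    if cx < 1:
                        cx = 1
                    if cx > ncell - 2:
                        cx = ncell - 2
                    if cy < 1:
                        cy = 1
                    if cy > ncell - 2:
                        cy = ncell - 2
                    cell = cx * ncell + cy
                    nxt[i] = head[cell]
                    head[cell] = i
            for g in range(n_act):
                if glut_active[g] == 0:
                    continue
                x = glut_pos[g, 0] + sig_glut * np.random.normal()
                y = glut_pos[g, 1] + sig_glut * np.random.normal()
                z = glut_pos[g, 2] + sig_glut * np.random.normal()
                if z < 0.0:
                    z = -z
                if z > cleft_h:
                    z = 2.0 * cleft_h - z
                if z < 0.0:
                    z = 0.0
                if x * x + y * y > esc_r2:
                    glut_active[g] = 0     # escaped the cleft, taken up
                    continue
                glut_pos[g, 0] = x
                glut_pos[g, 1] = y
                glut_pos[g, 2] = z
                gx = int((x + esc_r) / bind_r) + 1
                gy = int((y + esc_r) / bind_r) + 1
                if gx < 1:
                    gx = 1
                if gx > ncell - 2:
                    gx = ncell - 2
                if gy < 1:
                    gy = 1
                if gy > ncell - 2:
                    gy = ncell - 2
                bound = False
                for ox in range(-1, 2):
                    if bound:
                        break
                    for oy in range(-1, 2):
                        i = head[(gx + ox) * ncell + (gy + oy)]
                        while i >= 0:
                            dx = x - amp_pos[i, 0]
                            dy = y - amp_pos[i, 1]
                            if dx * dx + dy * dy <= bind_r2:
                                s = channel_state[i]
                                pb = bind_p[s]
                                if pb > 0.0 and np.random.random() < pb:
                                    channel_state[i] = bind_target[s]
                                    glut_active[g] = 0
                                    bound = True
                                    break
                            i = nxt[i]
                        if bound:
                            break

        # --- record open count ------------------------------------------
        n_open = 0
        for i in range(n_amp):
            if amp_state[i] != AMP_INTERNAL and channel_state[i] == open_state:
                n_open += 1
        open_out[local] = n_open
    return n_act
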