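"""Derived diffusion quantities of the built-in multishell PGSE protocols.

Loads the optimized ex-vivo ActiveAx protocol fixtures (G_max = 60-300 mT/m)
and prints, per shell, the diffusion time t_d = Delta - delta/3, the probed
length scale 1/q and the b-value; these are the quantities a protocol table
reports, and they show the optimizer's short-t_d / long-1/q versus long-t_d /
short-1/q shell pattern.
"""

from axodiff.protocol import table_fixtures, snr_at_te

for name in ("ActiveAx060", "ActiveAx140", "ActiveAx200", "ActiveAx300"):
    proto = table_fixtures()[name]
    te = proto.shells[0].TE
    snr = snr_at_te(20.0, 62.7, te, proto.assumed_T2)
    print(f"{name}: G_max={proto.G_max:.0f} mT/m, TE={te} ms, "
          f"SNR rel. to 20@62.7ms = {snr:.1f}, {proto.total_meas} measurements")
    for s in proto.shells:
        if s.is_b0:
            print(f"  b=0 shell: {s.n_meas} repetitions")
        else:
            print(f"  N={s.n_meas:3d}  G={s.G:5.0f} mT/m  delta={s.delta:5.1f} ms  "
                  f"Delta={s.Delta:5.1f} ms  b={s.b:7.0f} s/mm2  "
                  f"t_d={s.t_d:5.1f} ms  1/q={s.one_over_q_um:5.1f} um")
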