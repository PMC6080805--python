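"""Coexistence outcomes over the (p, c) plane of the cross-feeding toy.

For each combination of the producer's by-product export rate p and the
consumer's primary-uptake cap c, the analytical fixed-point solver reports
which strains persist: both (cross-feeding polymorphism), only P, only C
(the consumer no longer needs the producer), or neither (washout).
"""

import numpy as np

import crossfeed as cf

fx = cf.make_crossfeeding_fixture()
p_max = fx.p_max()
u_star = 5 * fx.D            # consumer persistence-alone threshold on S

p_grid = np.linspace(0.0, 1.1 * p_max, 8)
c_grid = np.linspace(0.0, 1.3 * u_star, 6)

symbol = {"both": "B", "P_only": "P", "C_only": "C", "neither": "."}
print(f"p_max = {p_max:.2f}, persistence-alone cap u* = {u_star:.2f}")
print("rows: p (down = more production); cols: c (right = more glucose for C)")
print("      " + "  ".join(f"{c:5.2f}" for c in c_grid))
for p in p_grid:
    row = []
    for c in c_grid:
        v = cf.steady_state_solve(
            fx.producer(p), fx.consumer(c), fx.medium, fx.primary,
            fx.secondary, p, D=fx.D, feed_conc=fx.feed,
            vmax=fx.vmax, km=fx.km, dt=0.1,
        )
        row.append(symbol[v.outcome])
    print(f"{p:5.1f} " + "  ".join(f"{s:>5}" for s in row))
print()
print("B = both persist, P/C = single strain, . = washout.  Coexistence is")
print("bounded above by p_max and on the right by the cap beyond which the")
print("consumer thrives on the primary alone and excludes the producer.")
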