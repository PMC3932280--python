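"""Bring your own functional response.

Any consumption-rate curve phi(N) can be certified against the five
structural hypotheses (smoothness, decreasing per-capita rate,
boundedness, bounded slope, monotone range beyond the carrying
capacity) and then used everywhere a built-in response is.  Here a
hump-shaped response is supplied as an expression string: it fails the
monotone-range hypothesis for a large carrying capacity and passes for
a small one.
"""

import predprey_rd as pp

spec = pp.response_from_expression("N/(4 + N**2)", N_max=100.0)
print(f"grid-estimated constants: Mtilde={spec.Mtilde:.4g}, "
      f"L={spec.L:.4g}, H={spec.H:.4g}, l={spec.l:.4g}")
# analytic values for comparison: Mtilde=1/4, L=1/4, H=1/4, l=2
# (grid estimates carry a 1% safety inflation)

for K in (1.5, 3.0):
    rep = pp.verify_hypotheses(spec, K, grid_n=20_000)
    print(f"K={K}: hypotheses (i)-(v) = "
          f"{[rep.h1, rep.h2, rep.h3, rep.h4, rep.h5]}  "
          f"all={rep.all_satisfied}")
# K=1.5 < l=2 passes; K=3 exceeds the increasing range and fails (v),
# so the permanence and stability theory no longer applies as-is.
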