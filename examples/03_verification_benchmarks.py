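"""Run the analytic verification suite for the shell solver.

Each benchmark has an independent closed-form oracle: constant-strain
patch test, Navier plate deflection, Kirchhoff plate fundamental
frequency, harmonic-oscillator period, discrete energy balance, explicit
vs implicit integrator agreement, and the explicit divergence guard.
"""

import orbishock as ob

results = ob.run_benchmarks()
width = max(len(r.name) for r in results)
for r in results:
    status = "PASS" if r.passed else "FAIL"
    print(f"{r.name:<{width}}  error {r.metric:10.3e}  tolerance {r.tolerance:8.0e}  {status}")

# Errors are dimensionless (relative to the oracle).  A healthy checkout
# passes everything with wide margins; the instability_guard line reports
# a *detected* divergence, which is the expected behaviour.
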