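"""Map simulation results to real time for a 1 kbp ssDNA/RNA chain.

Uses the unit mapping sigma = 3.4 A, m = 320 g/mol, kBT = 4.14e-21 J and
the empirical coil-expansion law tau_c ~ 0.18 N^2.36 to predict how long
a released genome takes to expand.
"""

from chainexpand.theory import (UnitMap, expansion_time, predicted_tau_c,
                                simulation_time_unit, to_real_units)

units = UnitMap()
tu = simulation_time_unit(units)
print(f"simulation time unit: {tu * 1e12:.3f} ps")

N = 1000
tau_c = predicted_tau_c(N, eta=1.0, a_c=0.18, exponent=2.36)
print(f"tau_c(N={N}) = {tau_c:.3g} tu = {to_real_units(tau_c) * 1e6:.2f} us")

tau = expansion_time(tau_c)
print(f"expansion time tau = 3 tau_c = {to_real_units(tau) * 1e6:.1f} us "
      "(the chain has then reached 99% of its final size)")
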