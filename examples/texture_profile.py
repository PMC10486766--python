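"""Extract texture-profile-analysis features from a double-compression curve.

Builds a synthetic two-cycle force trace with known peak force and areas,
segments it at the 25 gf trigger, and prints the classic TPA descriptor
set.  Adhesiveness — the magnitude of the negative force–time area as the
probe withdraws — is the objective proxy for sensory viscosity.
"""

from riceq import CurveSpec, compute_tpa, make_curve, segment_cycles

spec = CurveSpec(hardness=500.0, a3_magnitude=100.0, t1=2.0, t2=1.5,
                 cohesiveness_target=0.6, seed=7)
curve, truth = make_curve(spec)

seg = segment_cycles(curve, trigger=25.0)
feats = compute_tpa(curve, seg)

print(f"samples: {len(curve)}  span: {curve.time[-1]:.2f} s")
print(f"hardness      {feats.hardness:8.2f} gf   (truth {truth.hardness:.2f})")
print(f"adhesiveness  {feats.adhesiveness:8.2f} gf*s (truth {truth.adhesiveness:.2f})")
print(f"A1 / A2       {feats.A1:8.2f} / {feats.A2:.2f} gf*s")
print(f"T1 / T2       {feats.T1:8.2f} / {feats.T2:.2f} s")
print(f"springiness   {feats.springiness:8.3f}  = T2/T1")
print(f"cohesiveness  {feats.cohesiveness:8.3f}  = A2/A1")
print(f"gumminess     {feats.gumminess:8.2f}  = cohesiveness x hardness")
print(f"chewiness     {feats.chewiness:8.2f}  = gumminess x springiness")
print(f"resilience    {feats.resilience:8.3f}  = A5/A4")
print()
print("Sticky, high-viscosity rice pulls harder on the withdrawing probe,")
print("so its adhesiveness (the A3 magnitude) is larger.")
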