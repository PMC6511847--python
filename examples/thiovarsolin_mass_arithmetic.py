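"""Mass arithmetic for thioamidated peptides (the thiovarsolins).

Computes the theoretical [M+H]+ of the four thiovarsolins — N-acetylated
APR/GPR tripeptides with a thioamide at the Pro-Arg backbone bond, two of them
carrying one Arg side-chain desaturation — and demonstrates the H2S
neutral-loss screen that flags thioamide-bearing ions in MS2 data.
"""

from ripper.masses import (
    H2S,
    h2s_loss_screen,
    monoisotopic_mass,
    mz_protonated,
    thiovarsolin,
)

observed = {"A": 399.1818, "B": 401.1968, "C": 385.1652, "D": 387.1808}
print("variant  core  theoretical [M+H]+   observed    ppm")
for v in "ABCD":
    p = thiovarsolin(v)
    theo = mz_protonated(p)
    ppm = (observed[v] - theo) / theo * 1e6
    print(f"   {v}     {p.sequence}   {theo:12.4f}      {observed[v]:9.4f}  {ppm:+5.2f}")

b, d = mz_protonated(thiovarsolin("B")), mz_protonated(thiovarsolin("D"))
print(f"\nAla/Gly series offset (B - D): {b - d:.5f} Da  (one methyl, CH2)")

# a thioamide fragment ion loses H2S (33.988 Da) on fragmentation
prec = mz_protonated(thiovarsolin("B"))
frags = [prec - H2S, 227.0946, 156.1011]
hits = h2s_loss_screen({"thiovarsolin_B": (prec, frags)}, tol=0.01)
print(f"\nH2S-loss screen on a synthetic MS2 peak list: {len(hits)} hit(s)")
for h in hits:
    print(f"  {h.mz_high:.4f} -> {h.mz_low:.4f}  delta {h.delta:.4f} "
          f"(precursor involved: {h.involves_precursor})")
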