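"""vdW vs approximate SES cavity for an n-nonane-like chain.

The chain9 model is nine overlapping 2 Å spheres along a C–C backbone.
The solvent-excluding surface adds auxiliary spheres that block the
crevices a 1.3 Å probe cannot reach, so it exposes less area than the
plain union-of-spheres (vdW) surface.
"""

from cosmosol.cavity import AUXILIARY, CavityParams, build_cavity, build_ses_cavity
from cosmosol.solute import make_fixture

_, spheres = make_fixture("chain9", 0)

vdw = build_cavity(spheres, CavityParams(cavity_type="vdw", level="fine"))
ses = build_ses_cavity(spheres, CavityParams(cavity_type="ses", level="fine"))
n_aux = sum(1 for s in ses.spheres if s.origin == AUXILIARY)

print(f"vdW cavity : area {vdw.area:9.3f} A^2, volume {vdw.volume:9.3f} A^3, "
      f"{len(vdw.segments)} segments")
print(f"SES cavity : area {ses.area:9.3f} A^2, volume {ses.volume:9.3f} A^3, "
      f"{len(ses.segments)} segments, {n_aux} auxiliary spheres")
print(f"area ratio SES/vdW: {ses.area / vdw.area:.4f}  (< 1: the probe-"
      "inaccessible crevices are buried)")
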