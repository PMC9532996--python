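"""Export morphotype surfaces as STL and measure a surface pair.

Generated surfaces are lofted annular tubes for visualization; surface
input is used only for measurement (length, midshaft cortical thickness),
never as a solver mesh.
"""

import tempfile
from pathlib import Path

from cannonbone import midshaft_cortical_thickness, species_fixture
from cannonbone.morphology import SectionProfile
from cannonbone.stlio import (
    mesh_length,
    morphotype_surface,
    read_stl,
    tube_surface,
    write_stl,
)

out = Path(tempfile.mkdtemp()) / "euchoreutes.stl"
spec = species_fixture("euchoreutes")
write_stl(morphotype_surface(spec), out)
mesh = read_stl(out)
print(f"wrote {out} ({len(mesh.faces)} triangles)")
print(f"measured length: {mesh_length(mesh):.2f} mm (spec {spec.length} mm)")

# synthetic outer/inner surface pair: thickness by transverse sectioning
prof = SectionProfile.uniform(1.0, 0.4)
outer = tube_surface(20.0, prof, "outer")
inner = tube_surface(20.0, prof, "inner")
t = midshaft_cortical_thickness((outer, inner))
print(f"midshaft thickness from surface pair: {t:.3f} mm (true 0.400 mm)")
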