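"""From a triangulated scan mesh to a micro-DEM.

Builds a small mesh (here triangulated from a synthetic surface, standing
in for a PLY/OBJ/STL scan), picks the grid pitch from the mesh's vertex
spacing and rasterizes it by linear TIN interpolation.
"""

import tempfile
from pathlib import Path

from percmorph import (
    SyntheticSurfaceParams,
    generate_surface,
    median_vertex_spacing,
    rasterize_tin,
    read_mesh,
    write_ascii_grid,
    write_mesh,
)
from percmorph.synthetic import raster_to_mesh

surface, _ = generate_surface(
    SyntheticSurfaceParams(damage_class="natural", seed=3, n_rows=60, n_cols=60)
)
mesh = raster_to_mesh(surface)

with tempfile.TemporaryDirectory() as tmp:
    ply = write_mesh(mesh, Path(tmp) / "specimen.ply")
    mesh = read_mesh(ply, specimen_id="specimen", group_label="natural")

spacing = median_vertex_spacing(mesh)
print("mesh: %d vertices, %d faces" % (mesh.n_vertices, mesh.n_faces))
print("median vertex spacing: %.3f mm (used as default cell size)" % spacing)

dem = rasterize_tin(mesh)  # cell size and projection axis chosen automatically
print(
    "DEM: %d x %d cells @ %.3f mm, projected along %s"
    % (dem.n_rows, dem.n_cols, dem.cell_size, dem.projection_axis)
)
print("covered cells: %d" % (~dem.nodata_mask).sum())

out = Path(tempfile.gettempdir()) / "specimen_dem.asc"
write_ascii_grid(dem, out)
print("wrote", out, "(ESRI ASCII grid, openable in any GIS)")
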