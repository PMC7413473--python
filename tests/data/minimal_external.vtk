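# vtk DataFile Version 2.0
minimal externally written fixture (synthetic, hand-authored)
ASCII
DATASET RECTILINEAR_GRID
DIMENSIONS 3 2 1
X_COORDINATES 3 float
0.0 0.5 1.0
Y_COORDINATES 2 float
0.0 2.0
Z_COORDINATES 1 float
0.0
POINT_DATA 6
VECTORS velocity float
1 0 0
1 0 0
1 0 0
1 0 0
1 0 0
1 0 0
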