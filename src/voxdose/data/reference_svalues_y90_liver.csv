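sex,bmi,liver,lung,kidney,marrow
female,18.6,1.2085e-004,1.6692e-008,5.1755e-007,1.2834e-007
female,20.8,8.5090e-005,1.7210e-007,6.9404e-007,3.1386e-008
female,22.1,9.2387e-005,2.5969e-007,2.8099e-007,4.6769e-008
female,26.8,9.5030e-005,7.5511e-009,5.6558e-007,3.1865e-008
female,30.3,8.6134e-005,3.0210e-007,1.2805e-007,1.1142e-007
female,34.7,7.8204e-005,4.8910e-007,4.4929e-007,3.2973e-008
male,23.0,8.6110e-005,2.7157e-007,3.3380e-007,7.1842e-008
male,24.9,7.8633e-005,3.7746e-007,1.3852e-007,3.4974e-008
male,27.1,9.2373e-005,1.9722e-007,6.2601e-007,6.0759e-009
male,28.3,8.4301e-005,3.5794e-007,2.4988e-007,4.6876e-008
male,29.3,6.6163e-005,6.0479e-009,3.9694e-007,1.7263e-008
male,34.5,6.1598e-005,1.5001e-007,9.7855e-008,3.1512e-008
male,35.8,6.5184e-005,4.1659e-008,7.1693e-008,4.3151e-008
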