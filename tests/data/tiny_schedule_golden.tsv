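# {"mode": "SR", "j_hz": 35.0, "delta_a_s": 1e-05, "delta_b_s": 0.002, "t1_max_s": 0.038, "n_increments": 8, "base_scans": 4, "switch_margin_s": 0.002, "rounding_mode": "nearest-integer", "round_multiple": 2, "boost_cap": "cap-after-1/J"}
index	t1_s	delta_used	t_eff_s	phase_sign	n_scans	residual
0	0.000000000	A	0.000020000	1	4	1.000002418
1	0.005428571	A	0.005448571	1	5	0.968707726
2	0.010857143	A	0.010877143	1	11	0.993327628
3	0.016285714	B	0.020285714	-1	7	0.932325004
4	0.021714286	B	0.025714286	-1	4	1.051462224
5	0.027142857	B	0.031142857	-1	4	1.000000000
6	0.032571429	B	0.036571429	-1	4	1.000000000
7	0.038000000	B	0.042000000	-1	4	1.000000000
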