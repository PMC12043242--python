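# phi_min phi_max step
# -180 180 10
INF INF INF INF INF INF INF INF INF INF 2.5 1.5 1.5 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF 2.5 2.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF 2.5 2.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF 2.5 1.5 1.5 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF 2.5 1.5 0.408163 0.382653 0.484694 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF 2.5 1.5 0.306122 0.153061 0.127551 0.229592 0.459184 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF 2.5 1.5 0.459184 0.178571 0.0255102 0 0.102041 0.331633 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF 2.5 1.5 0.459184 0.178571 0.0255102 0 0.102041 0.331633 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF 2.5 1.5 0.306122 0.153061 0.127551 0.229592 0.459184 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF 2.5 1.5 0.408163 0.382653 0.484694 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF 2.5 1.5 1.5 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF 2.5 2.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF 2.5 2.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF 2.5 1.5 1.5 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF 2.5 1.5 0.408163 0.382653 0.484694 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF 2.5 1.5 0.306122 0.153061 0.127551 0.229592 0.459184 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF 2.5 1.5 0.459184 0.178571 0.0255102 0 0.102041 0.331633 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF 2.5 1.5 0.459184 0.178571 0.0255102 0 0.102041 0.331633 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF 2.5 1.5 0.306122 0.153061 0.127551 0.229592 0.459184 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF 2.5 1.5 0.408163 0.382653 0.484694 1.5 2.5 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
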