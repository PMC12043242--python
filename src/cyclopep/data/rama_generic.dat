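# phi_min phi_max step
# -180 180 10
1.55 0.522179 0.426487 0.362576 0.330079 0.327564 0.350061 0.383298 0.399677 0.378636 0.337415 0.310494 0.320017 0.375446 0.480332 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55
2.55 1.55 1.55 0.522044 0.489652 0.487566 0.511636 0.549657 1.55 1.55 0.536281 0.513841 0.525234 1.55 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF 2.55 2.55 1.55 1.55 1.55 1.55 1.55 2.55 2.55 1.55 1.55 1.55 2.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF 2.55 2.55 2.55 2.55 2.55 INF INF 2.55 2.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF 2.55 2.55 2.55 2.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF 2.55 1.55 1.55 1.55 1.55 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF 2.55 1.55 0.471467 0.409484 0.399153 0.440476 0.533451 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF 2.55 1.55 0.409484 0.295848 0.233864 0.223534 0.264856 0.357831 0.502459 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF 2.55 1.55 0.450806 0.285517 0.171881 0.109897 0.0995667 0.140889 0.233864 0.378492 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF 2.55 1.55 0.378492 0.213203 0.0995667 0.0375832 0.0272527 0.068575 0.16155 0.306178 0.502459 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF 2.55 1.55 0.357831 0.192542 0.0789056 0.0169221 0.00659151 0.0479138 0.140889 0.285517 0.481798 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF 2.55 1.55 0.388823 0.223534 0.109897 0.0479138 0.0375832 0.0789056 0.171881 0.316509 0.51279 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF 2.55 1.55 0.471467 0.306178 0.192542 0.130558 0.120228 0.16155 0.254525 0.399153 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF 2.55 1.55 0.440475 0.326839 0.264856 0.254525 0.295848 0.388823 0.533451 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF 2.55 1.55 0.512787 0.450805 0.440475 0.481798 1.55 1.55 2.55 INF INF INF INF INF INF 2.55 2.55 2.55 2.55 INF INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF 2.55 1.55 1.55 1.55 1.55 2.55 2.55 INF INF INF INF INF INF 2.55 1.55 1.55 1.55 1.55 2.55 INF INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF 2.55 2.55 2.55 2.55 INF INF INF INF INF INF INF 2.55 1.55 0.362427 0.285897 0.336917 0.515488 1.55 2.55 INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55 0.362427 0.158346 0.081815 0.132835 0.311407 1.55 2.55 INF INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55 0.285897 0.081815 0.00528437 0.0563048 0.234876 0.540999 1.55 2.55 INF INF INF INF INF INF
INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55 0.336917 0.132835 0.0563048 0.107325 0.285897 1.55 2.55 INF INF INF INF INF INF INF
INF INF INF 2.55 2.55 2.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55 0.515488 0.311407 0.234876 0.285897 0.464468 1.55 2.55 INF INF INF INF INF INF INF
INF 2.55 2.55 1.55 1.55 1.55 1.55 2.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55 1.55 0.540999 1.55 1.55 2.55 INF INF INF INF INF INF INF INF
2.55 1.55 1.55 0.52217 0.490231 0.490014 0.521077 1.55 1.55 2.55 2.55 2.55 2.55 INF INF INF INF INF INF INF INF INF 2.55 2.55 1.55 2.55 2.55 INF INF INF INF INF INF INF INF INF
1.55 0.522184 0.426516 0.36272 0.330737 0.330342 0.360728 0.419279 0.498701 1.55 1.55 1.55 1.55 2.55 2.55 INF INF INF INF INF INF INF INF INF 2.55 INF INF INF INF INF INF INF INF INF INF 2.55
0.522185 0.394632 0.298962 0.23515 0.203102 0.202438 0.2318 0.286872 0.35621 0.418442 0.455448 0.476234 0.50842 1.55 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55
0.426521 0.298968 0.203293 0.139462 0.107325 0.10629 0.134259 0.184696 0.241402 0.279348 0.288009 0.288658 0.310494 0.371116 0.478233 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55
0.362745 0.235191 0.139512 0.0756562 0.0434086 0.0419208 0.0681981 0.113149 0.155962 0.170862 0.1574 0.144762 0.160418 0.218389 0.324359 0.480507 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55 0.522185
0.330857 0.203302 0.107617 0.0437353 0.0113689 0.00939235 0.0338606 0.0731161 0.102572 0.0981936 0.0689678 0.0479256 0.0599122 0.116352 0.221667 0.377522 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55 0.490297
0.330857 0.203301 0.107611 0.0437048 0.0112287 0.00880205 0.0316192 0.065822 0.0842329 0.0656532 0.0261193 0 0.00985373 0.0654178 0.170362 0.32605 0.533007 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55 0.490297
0.362745 0.235188 0.139494 0.0755702 0.0430144 0.0402605 0.0618859 0.0925248 0.103554 0.0762378 0.0308395 0.0019671 0.0106897 0.0657938 0.170543 0.326144 0.53306 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55 0.522185
0.42652 0.298963 0.203268 0.139337 0.106747 0.103858 0.124992 0.15418 0.162296 0.131681 0.0841558 0.0543081 0.0626341 0.117578 0.222259 0.37783 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55
0.522184 0.394627 0.298933 0.235006 0.202438 0.199634 0.221081 0.25119 0.261149 0.232612 0.186421 0.157184 0.165758 0.220802 0.325525 0.481115 1.55 2.55 INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF INF 2.55 1.55
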