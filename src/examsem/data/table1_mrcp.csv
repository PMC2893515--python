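exam,diet,n_scored_items,alpha,sd,sem
Part1,2003/3,199,0.89,9.23,3.09
Part1,2004/1,200,0.89,9.70,3.10
Part1,2004/2,200,0.89,10.46,3.14
Part1,2004/3,200,0.91,9.68,3.14
Part1,2005/1,200,0.89,10.67,3.16
Part1,2005/2,200,0.92,9.27,3.08
Part1,2005/3,195,0.90,10.19,3.21
Part1,2006/1,194,0.92,11.08,3.23
Part1,2006/2,193,0.90,10.09,3.24
Part1,2006/3,195,0.89,9.83,3.27
Part1,2007/1,195,0.92,11.49,3.25
Part1,2007/2,195,0.91,10.59,3.25
Part1,2007/3,195,0.92,11.51,3.26
Part1,2008/1,184,0.93,11.90,3.15
Part1,2008/2,185,0.91,11.13,3.34
Part1,2008/3,185,0.92,11.59,3.28
Part2,2002/3,149,0.79,7.67,3.51
Part2,2003/1,146,0.76,7.43,3.66
Part2,2003/2,150,0.73,6.94,3.58
Part2,2003/3,152,0.76,7.24,3.52
Part2,2004/1,149,0.75,7.10,3.55
Part2,2004/2,177,0.83,8.05,3.28
Part2,2004/3,183,0.78,6.94,3.26
Part2,2005/1,181,0.76,6.77,3.30
Part2,2005/2,180,0.80,7.33,3.25
Part2,2005/3,253,0.83,6.73,2.78
Part2,2006/1,250,0.81,6.46,2.82
Part2,2006/2,251,0.85,7.20,2.75
Part2,2006/3,253,0.82,6.52,2.80
Part2,2007/1,249,0.77,5.84,2.83
Part2,2007/2,263,0.84,6.89,2.72
Part2,2007/3,262,0.85,7.13,2.76
Part2,2008/1,264,0.82,6.52,2.76
Part2,2008/2,266,0.85,6.95,2.73
Part2,2008/3,259,0.84,6.99,2.77
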