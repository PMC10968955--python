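node_i,node_j,weight
D,ES,0.000
ANX,ES,0.000
ANX,D,0.590
M,ES,0.072
M,D,0.000
M,ANX,0.000
ADHD,ES,0.062
ADHD,D,0.191
ADHD,ANX,0.175
ADHD,M,0.128
PLEs,ES,0.113
PLEs,D,0.046
PLEs,ANX,0.000
PLEs,M,0.279
PLEs,ADHD,0.027
OCD,ES,0.000
OCD,D,0.077
OCD,ANX,0.061
OCD,M,0.000
OCD,ADHD,0.246
OCD,PLEs,0.398
Age,ES,0.000
Age,D,0.000
Age,ANX,0.000
Age,M,0.065
Age,ADHD,0.000
Age,PLEs,0.000
Age,OCD,0.000
Ed,ES,0.057
Ed,D,0.000
Ed,ANX,0.000
Ed,M,0.000
Ed,ADHD,0.000
Ed,PLEs,0.000
Ed,OCD,0.000
Ed,Age,0.304
G,ES,0.177
G,D,0.000
G,ANX,0.000
G,M,0.000
G,ADHD,0.000
G,PLEs,0.000
G,OCD,0.082
G,Age,0.052
G,Ed,0.000
Emp,ES,0.000
Emp,D,0.000
Emp,ANX,0.000
Emp,M,0.000
Emp,ADHD,0.000
Emp,PLEs,0.000
Emp,OCD,0.000
Emp,Age,0.000
Emp,Ed,0.445
Emp,G,0.355
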