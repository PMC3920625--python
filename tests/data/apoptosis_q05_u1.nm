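mdp

const double q = 0.5;

module CSPBNm1
  d1 : [1..2] init 1;
  [CSPBN] d1=1 -> 0.6*q + (1-q) : (d1'=1) + 0.4*q : (d1'=2);
  [CSPBN] d1=2 -> 0.6*q : (d1'=1) + 0.4*q + (1-q) : (d1'=2);
endmodule

module CSPBNm2
  d2 : [1..2] init 1;
  [CSPBN] d2=1 -> 0.7*q + (1-q) : (d2'=1) + 0.3*q : (d2'=2);
  [CSPBN] d2=2 -> 0.7*q : (d2'=1) + 0.3*q + (1-q) : (d2'=2);
endmodule

module CSPBNm3
  d3 : [1..2] init 1;
  [CSPBN] d3=1 -> 0.8*q + (1-q) : (d3'=1) + 0.2*q : (d3'=2);
  [CSPBN] d3=2 -> 0.8*q : (d3'=1) + 0.2*q + (1-q) : (d3'=2);
endmodule

module CSPBN1
  x1 : [0..1] init 1;
  [CSPBN] d1=1 -> 1.0 : (x1'=u - u*x2);
  [CSPBN] d1=2 -> 1.0 : (x1'=x1);
endmodule

module CSPBN2
  x2 : [0..1] init 1;
  [CSPBN] d2=1 -> 1.0 : (x2'=x3 - x1*x3);
  [CSPBN] d2=2 -> 1.0 : (x2'=x2);
endmodule

module CSPBN3
  x3 : [0..1] init 1;
  [CSPBN] d3=1 -> 1.0 : (x3'=u + x2 - u*x2);
  [CSPBN] d3=2 -> 1.0 : (x3'=x3);
endmodule

module input1
  u : [0..1] init 1;
  [CSPBN] u=0 -> (u'=0);
  [CSPBN] u=0 -> (u'=1);
  [CSPBN] u=1 -> (u'=0);
  [CSPBN] u=1 -> (u'=1);
endmodule

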