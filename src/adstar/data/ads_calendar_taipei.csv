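# Asian dust storm days reaching Taipei City, 1997-2007, as identified by the
# Chinese Culture University (1997-1999) and the Taiwan EPA (2000-2007).
# One row per year: year, then comma-separated day entries "M/D" or "M/D-M/D"
# (ranges inclusive).
1997,1/1, 3/7-3/8, 3/30, 4/8, 4/21, 4/27-4/28
1998,1/4, 2/13, 2/18-2/19, 3/7, 3/19, 3/30, 4/4, 4/15, 4/17-4/19, 4/24-4/26, 5/1, 11/5, 12/15
1999,1/27, 2/19, 3/8-3/9, 3/26, 4/7, 4/13, 11/25
2000,3/6-3/7, 3/24-3/25, 3/28-3/29, 4/6, 4/8, 4/10-4/11, 4/15-4/16, 4/22, 4/27-4/28, 5/1, 5/3-5/4, 5/13-5/18, 12/24
2001,1/13-1/15, 2/1, 2/16-2/17, 2/21-2/25, 3/1-3/7, 4/12-4/14, 5/1-5/2
2002,2/11-2/12, 3/6-3/9, 3/23-3/24, 3/31-4/1, 4/8-4/15, 4/17-4/19
2003,2/18-2/19, 2/23-2/25, 3/6-3/9, 3/25-3/30, 4/25-4/28
2004,1/1-1/4, 1/13-1/14, 1/21-1/22, 1/24-1/25, 2/6-2/12, 2/14-2/16, 2/26-2/27, 3/3-3/7, 4/2-4/4
2005,3/18-3/19, 11/29-11/30, 12/21-12/22
2006,3/19-3/20, 3/29-3/30, 4/20-4/21
2007,1/28-1/29, 4/2-4/3, 4/17-4/18, 12/30-12/31
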